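"""Saliency decomposition, attention pooling, MLP head and robust loss."""

import numpy as np
import pytest

from pestfusion.nn import Tensor, no_grad
from pestfusion.regression import (GlobalAggregator, RegressionHead,
                                   SaliencyDecomposition, lipschitz_bound,
                                   lipschitz_probe, robust_loss)

rng = np.random.default_rng(55)


# -- decomposition -----------------------------------------------------------

def test_decomposition_reconstruction_identity():
    dec = SaliencyDecomposition(8, np.random.default_rng(0))
    s = Tensor(rng.standard_normal((3, 10, 8)))  # float64 for the oracle
    sp, sm, mask = dec(s)
    assert np.max(np.abs(sp.data + sm.data - s.data)) < 1e-12
    assert np.all((mask.data > 0) & (mask.data < 1))


def test_decomposition_zero_weights_split_in_half():
    dec = SaliencyDecomposition(8, np.random.default_rng(0))
    dec.net[0].weight.data[:] = 0.0
    dec.net[0].bias.data[:] = 0.0
    s = Tensor(rng.standard_normal((2, 5, 8)).astype(np.float32))
    sp, sm, mask = dec(s)
    assert np.allclose(mask.data, 0.5)
    assert np.allclose(sp.data, s.data / 2, atol=1e-7)
    assert np.allclose(sm.data, s.data / 2, atol=1e-7)


def test_decomposition_saturated_mask_suppresses_complement():
    dec = SaliencyDecomposition(4, np.random.default_rng(0))
    dec.net[0].weight.data[:] = 0.0
    dec.net[0].bias.data[:] = 60.0   # sigmoid -> 1
    s = Tensor(rng.standard_normal((1, 6, 4)).astype(np.float32))
    _, sm, _ = dec(s)
    assert np.max(np.abs(sm.data)) < 1e-6


# -- global aggregation ------------------------------------------------------

def test_aggregator_attention_rows_sum_to_one():
    agg = GlobalAggregator(8, 2, np.random.default_rng(0))
    sp = Tensor(rng.standard_normal((2, 5, 8)).astype(np.float32))
    sm = Tensor(rng.standard_normal((2, 5, 8)).astype(np.float32))
    agg(sp, sm)
    assert np.allclose(agg.last_weights.sum(axis=-1), 1.0, atol=1e-6)


def test_aggregator_zero_values_identity_ffn_reduces_to_layernorm():
    agg = GlobalAggregator(8, 2, np.random.default_rng(0))
    agg.attn.w_v.weight.data[:] = 0.0
    for layer in (agg.ffn.fc1, agg.ffn.fc2):
        layer.weight.data[:] = 0.0
        layer.bias.data[:] = 0.0
    sp = Tensor(rng.standard_normal((1, 4, 8)).astype(np.float32))
    g = agg(sp, None)
    from pestfusion.nn import LayerNorm
    expected = LayerNorm(8)(Tensor(
        agg.global_token.data[None, None, :]))[:, 0, :]
    assert np.allclose(g.data, expected.data, atol=1e-6)


def test_aggregator_single_query_two_keys_matches_bruteforce():
    d = 2
    agg = GlobalAggregator(d, 1, np.random.default_rng(0))
    for w in (agg.attn.w_q, agg.attn.w_k, agg.attn.w_v, agg.attn.w_o):
        w.weight.data = np.eye(d, dtype=np.float32)
    keys = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
    agg.global_token.data = np.array([2.0, 0.0], dtype=np.float32)
    sp = Tensor(keys[:, :1])
    sm = Tensor(keys[:, 1:])
    agg(sp, sm)
    q = np.array([2.0, 0.0])
    logits = (keys[0] @ q) / np.sqrt(d)
    w = np.exp(logits - logits.max())
    w /= w.sum()
    assert np.allclose(agg.last_weights[0, 0, 0], w, atol=1e-6)


# -- regression head ---------------------------------------------------------

def test_head_all_zero_weights_predicts_zero():
    head = RegressionHead(8, np.random.default_rng(0), dropout=0.0)
    for layer in (head.fc1, head.fc2, head.fc3):
        layer.weight.data[:] = 0.0
        layer.bias.data[:] = 0.0
    out = head(Tensor(rng.standard_normal((3, 8)).astype(np.float32)))
    assert np.allclose(out.data, 0.0)


def test_head_identity_chain_passes_value_through():
    head = RegressionHead(4, np.random.default_rng(0), dropout=0.0,
                          hidden=(2, 1))
    # route the first input coordinate through with unit weights
    head.fc1.weight.data[:] = 0.0
    head.fc1.weight.data[0, 0] = 1.0
    head.fc2.weight.data[:] = 0.0
    head.fc2.weight.data[0, 0] = 1.0
    head.fc3.weight.data[:] = 0.0
    head.fc3.weight.data[0, 0] = 1.0
    for layer in (head.fc1, head.fc2, head.fc3):
        layer.bias.data[:] = 0.0
    g = np.zeros((1, 4), np.float32)
    g[0, 0] = 0.7
    assert head(Tensor(g)).data[0] == pytest.approx(0.7, abs=1e-6)


def test_head_inference_reproducible_and_dropout_only_in_training():
    head = RegressionHead(8, np.random.default_rng(0), dropout=0.5)
    g = Tensor(rng.standard_normal((4, 8)).astype(np.float32))
    head.eval()
    a = head(g).data
    b = head(g).data
    assert np.array_equal(a, b)
    head.train()
    c = head(g).data
    d = head(g).data
    assert not np.array_equal(c, d)  # stochastic masks differ


def test_head_rejects_non_decreasing_hidden_dims():
    with pytest.raises(ValueError):
        RegressionHead(4, np.random.default_rng(0), hidden=(4, 2))


# -- robust loss -------------------------------------------------------------

def test_robust_loss_branch_values():
    p = Tensor(np.array([0.5]))
    t = np.array([0.0])
    assert robust_loss(p, t, eps=1.0).item() == pytest.approx(0.125)
    p2 = Tensor(np.array([2.0]))
    assert robust_loss(p2, t, eps=1.0).item() == pytest.approx(1.5)
    assert robust_loss(Tensor(np.array([3.0])), np.array([3.0]),
                       eps=1.0).item() == 0.0
    with pytest.raises(ValueError):
        robust_loss(p, t, eps=0.0)


@pytest.mark.parametrize("eps", [0.25, 0.5, 1.0, 2.0, 5.0])
def test_robust_loss_continuous_at_branch_point(eps):
    quad = 0.5 * eps ** 2
    lin = eps * (eps - 0.5 * eps)
    assert quad == pytest.approx(lin)
    for side in (-1e-9, 0.0, 1e-9):
        val = robust_loss(Tensor(np.array([eps + side])), np.array([0.0]),
                          eps=eps).item()
        assert val == pytest.approx(quad, abs=1e-6)


def test_robust_loss_symmetric_in_error_sign():
    for e in rng.uniform(0, 3, size=20):
        lp = robust_loss(Tensor(np.array([e])), np.array([0.0])).item()
        lm = robust_loss(Tensor(np.array([-e])), np.array([0.0])).item()
        assert lp == pytest.approx(lm)


def test_robust_loss_gradient_matches_finite_differences_and_is_bounded():
    eps_loss = 1.3
    for e in np.concatenate([rng.uniform(-4, 4, 30), [1.29, 1.31, -1.3]]):
        p = Tensor(np.array([float(e)]), requires_grad=True)
        robust_loss(p, np.array([0.0]), eps=eps_loss).backward()
        h = 1e-6
        num = (robust_loss(Tensor(np.array([e + h])), np.array([0.0]),
                           eps=eps_loss).item()
               - robust_loss(Tensor(np.array([e - h])), np.array([0.0]),
                             eps=eps_loss).item()) / (2 * h)
        assert p.grad[0] == pytest.approx(num, abs=1e-5)
        assert abs(p.grad[0]) <= eps_loss + 1e-9


# -- Lipschitz probe ---------------------------------------------------------

def test_lipschitz_zero_weights_zero_bound():
    head = RegressionHead(4, np.random.default_rng(0), dropout=0.0)
    for layer in (head.fc1, head.fc2, head.fc3):
        layer.weight.data[:] = 0.0
    report = lipschitz_probe(head, 100, np.random.default_rng(1))
    assert report["kappa_bound"] == 0.0
    assert report["max_ratio"] == 0.0


def test_lipschitz_scalar_chain_exact():
    head = RegressionHead(4, np.random.default_rng(0), dropout=0.0,
                          hidden=(2, 1))
    head.fc1.weight.data[:] = 0.0
    head.fc1.weight.data[0, 0] = 2.0
    head.fc2.weight.data[:] = 0.0
    head.fc2.weight.data[0, 0] = 3.0
    head.fc3.weight.data[:] = np.array([[0.5]], dtype=np.float32)
    for layer in (head.fc1, head.fc2, head.fc3):
        layer.bias.data[:] = 0.0
    assert lipschitz_bound(head) == pytest.approx(3.0)
    # on the positive ray the chain is linear with slope 3
    g1 = np.array([[1.0, 0.0, 0.0, 0.0]], np.float32)
    g2 = np.array([[2.0, 0.0, 0.0, 0.0]], np.float32)
    with no_grad():
        f1 = head(Tensor(g1)).data[0]
        f2 = head(Tensor(g2)).data[0]
    assert abs(f2 - f1) / 1.0 == pytest.approx(3.0, abs=1e-6)


def test_lipschitz_empirical_ratios_below_operator_norm_product():
    head = RegressionHead(16, np.random.default_rng(3), dropout=0.0)
    report = lipschitz_probe(head, 10000, np.random.default_rng(4))
    assert report["all_within_bound"]
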