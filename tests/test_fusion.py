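"""Cross-modal attention, alignment loss and conditional modulation."""

import numpy as np
import pytest

from pestfusion.fusion import (ChannelModulator, CrossModalAlign,
                               EnvContextEncoder, SpatialGate,
                               alignment_loss, modulation_norm_bound)
from pestfusion.nn import (LayerNorm, MultiHeadAttention, SGD, Tensor,
                           no_grad)

rng = np.random.default_rng(99)


def _tokens(b, n, d):
    return Tensor(rng.standard_normal((b, n, d)).astype(np.float32))


# -- cross-modal attention ---------------------------------------------------

def test_zero_query_projection_gives_uniform_attention():
    align = CrossModalAlign(8, 2, np.random.default_rng(0))
    align.attn.w_q.weight.data[:] = 0.0
    v = _tokens(2, 3, 8)
    align(v, _tokens(2, 4, 8), _tokens(2, 2, 8))
    w = align.last_weights
    assert w.shape == (2, 2, 3, 6)
    assert np.allclose(w, 1.0 / 6.0, atol=1e-6)


def test_zero_value_projection_reduces_to_layernorm_residual():
    align = CrossModalAlign(8, 2, np.random.default_rng(0))
    align.attn.w_v.weight.data[:] = 0.0
    v = _tokens(2, 3, 8)
    out = align(v, _tokens(2, 4, 8), None)
    expected = LayerNorm(8)(v)
    assert np.allclose(out.data, expected.data, atol=1e-6)


def test_hand_computed_two_key_attention():
    """1 query, 2 keys, logits (ln 2, 0), no scaling -> weights (2/3, 1/3)."""
    d = 2
    attn = MultiHeadAttention(d, 1, np.random.default_rng(0), scaled=False)
    attn.w_q.weight.data = np.eye(d, dtype=np.float32)
    attn.w_k.weight.data = np.eye(d, dtype=np.float32)
    attn.w_v.weight.data = np.eye(d, dtype=np.float32)
    attn.w_o.weight.data = np.eye(d, dtype=np.float32)
    q = Tensor(np.array([[[1.0, 0.0]]], dtype=np.float32))
    kv = Tensor(np.array([[[np.log(2.0), 5.0], [0.0, -1.0]]],
                         dtype=np.float32))
    out = attn(q, kv)
    assert np.allclose(attn.last_weights[0, 0, 0], [2 / 3, 1 / 3], atol=1e-6)
    expected = 2 / 3 * kv.data[0, 0] + 1 / 3 * kv.data[0, 1]
    assert np.allclose(out.data[0, 0], expected, atol=1e-5)


def test_attention_rows_sum_to_one():
    align = CrossModalAlign(16, 4, np.random.default_rng(1))
    for _ in range(20):
        align(_tokens(2, 5, 16), _tokens(2, 7, 16), _tokens(2, 3, 16))
        sums = align.last_weights.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)


def test_attention_invariant_to_key_value_permutation():
    align = CrossModalAlign(8, 2, np.random.default_rng(2))
    v = _tokens(1, 4, 8)
    e, t = _tokens(1, 5, 8), _tokens(1, 3, 8)
    with no_grad():
        out1 = align(v, e, t).data
    perm = rng.permutation(8)
    kv = np.concatenate([e.data, t.data], axis=1)[:, perm]
    with no_grad():
        out2 = align(v, Tensor(kv), None).data
    assert np.allclose(out1, out2, atol=1e-5)


def test_d_not_divisible_by_heads_rejected():
    with pytest.raises(ValueError):
        MultiHeadAttention(10, 4, np.random.default_rng(0))


# -- alignment loss ----------------------------------------------------------

def test_alignment_loss_zero_iff_means_coincide():
    base = rng.standard_normal((1, 4, 8)).astype(np.float32)
    shuffled = base[:, ::-1].copy()  # same mean, different tokens
    loss = alignment_loss(Tensor(base), Tensor(shuffled), Tensor(base))
    assert loss.item() == pytest.approx(0.0, abs=1e-10)
    shifted = base + 0.5
    assert alignment_loss(Tensor(base), Tensor(shifted),
                          Tensor(base)).item() > 0.01


def test_alignment_loss_direct_arithmetic():
    """mu_v=(1,0), mu_e=(0,0), mu_t=(0,1) -> 1 + 2 = 3."""
    v = Tensor(np.array([[[1.0, 0.0]]], dtype=np.float32))
    e = Tensor(np.array([[[0.0, 0.0]]], dtype=np.float32))
    t = Tensor(np.array([[[0.0, 1.0]]], dtype=np.float32))
    assert alignment_loss(v, e, t).item() == pytest.approx(3.0)


def test_alignment_loss_descends_under_gradient_steps():
    v = _tokens(2, 6, 8)
    e0 = rng.standard_normal((2, 4, 8)).astype(np.float32)
    t0 = rng.standard_normal((2, 3, 8)).astype(np.float32)
    shift_e = Tensor(np.zeros((2, 1, 8), np.float32), requires_grad=True)
    shift_t = Tensor(np.zeros((2, 1, 8), np.float32), requires_grad=True)
    opt = SGD([shift_e, shift_t], lr=0.05)
    values = []
    for _ in range(50):
        loss = alignment_loss(v, Tensor(e0) + shift_e, Tensor(t0) + shift_t)
        values.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert all(b < a for a, b in zip(values, values[1:]))


# -- environment context and modulation --------------------------------------

def test_env_context_shapes_and_mean():
    enc = EnvContextEncoder(5, 16, np.random.default_rng(0))
    u, z = enc(Tensor(rng.standard_normal((3, 24, 5))))  # float64 oracle
    assert u.shape == (3, 24, 16)
    assert z.shape == (3, 16)
    # z equals the column mean of U
    assert np.max(np.abs(z.data - u.data.mean(axis=1))) < 1e-12


def test_env_context_rejects_window_shorter_than_kernel():
    enc = EnvContextEncoder(5, 8, np.random.default_rng(0))
    with pytest.raises(ValueError):
        enc(Tensor(np.zeros((1, 2, 5), np.float32)))


def test_channel_modulation_zero_weights_gives_three_halves():
    mod = ChannelModulator(8, np.random.default_rng(0))
    for layer in (mod.gate, mod.bias):
        layer.weight.data[:] = 0.0
        layer.bias.data[:] = 0.0
    f = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
    z = Tensor(rng.standard_normal((2, 8)).astype(np.float32))
    out, a, b = mod(f, z)
    assert np.allclose(a.data, 0.5)
    assert np.allclose(out.data, 1.5 * f.data, atol=1e-6)


def test_channel_modulation_gate_zero_limit_is_identity():
    mod = ChannelModulator(4, np.random.default_rng(0))
    mod.gate.weight.data[:] = 0.0
    mod.gate.bias.data[:] = -50.0   # sigmoid -> 0
    mod.bias.weight.data[:] = 0.0
    mod.bias.bias.data[:] = 0.0
    f = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
    out, a, _ = mod(f, Tensor(np.zeros((1, 4), np.float32)))
    assert np.allclose(out.data, f.data, atol=1e-5)


def test_channel_mismatch_rejected():
    mod = ChannelModulator(4, np.random.default_rng(0))
    with pytest.raises(ValueError):
        mod(Tensor(np.zeros((1, 8, 3, 3), np.float32)),
            Tensor(np.zeros((1, 4), np.float32)))


def test_modulated_norm_bound_over_random_draws():
    """|F~|_F <= (1 + |a|_inf)|F|_F + sqrt(HW)|b|_2 on every trial."""
    mod = ChannelModulator(8, np.random.default_rng(0))
    for _ in range(200):
        f = Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32) * 3)
        z = Tensor(rng.standard_normal((1, 8)).astype(np.float32) * 2)
        with no_grad():
            out, a, b = mod(f, z)
        assert 0.0 < a.data.min() and a.data.max() < 1.0
        bound = modulation_norm_bound(f.data[0], a.data[0], b.data[0])
        assert np.linalg.norm(out.data[0]) <= bound + 1e-5


def test_spatial_gate_range_and_contraction():
    gate = SpatialGate(8, np.random.default_rng(0))
    # zero conv weights -> gate 0.5 everywhere
    gate.conv.weight.data[:] = 0.0
    gate.conv.bias.data[:] = 0.0
    f = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
    out, m = gate(f)
    assert np.allclose(m.data, 0.5)
    assert np.allclose(out.data, 0.5 * f.data, atol=1e-7)
    # random weights: gate in (0,1) and the output norm never grows
    gate2 = SpatialGate(8, np.random.default_rng(1))
    for _ in range(100):
        f = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32) * 2)
        with no_grad():
            out, m = gate2(f)
        assert 0.0 < m.data.min() and m.data.max() < 1.0
        assert np.linalg.norm(out.data) <= np.linalg.norm(f.data)
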