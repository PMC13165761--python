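"""Saliency decomposition, global aggregation and the density regressor.

The fused token sequence S is softly split by a per-token sigmoid mask into
a density-sensitive part S+ = M * S and its complement S- = (1 - M) * S
(so S+ + S- reconstructs S exactly).  A learned global token, together with
S+, queries [S+; S-] through multi-head attention; the global token's
post-attention state, after layer normalization and a feed-forward block,
is the pooled representation g.  A three-layer progressively compressed MLP
maps g to the scalar density.  Training uses a smooth-L1 (Huber-style)
robust objective: quadratic inside +/- eps, linear outside, continuous and
once-differentiable at the branch point, with gradient magnitude <= eps.
"""

from __future__ import annotations

import numpy as np

from .nn import (Dropout, FeedForward, LayerNorm, Linear, Module,
                 MultiHeadAttention, Tensor, concatenate, where)

__all__ = ["SaliencyDecomposition", "GlobalAggregator", "RegressionHead",
           "robust_loss", "mse_loss", "lipschitz_bound", "lipschitz_probe"]


class SaliencyDecomposition(Module):
    """Per-token sigmoid mask from a single affine layer (the lightweight
    mapping network); deeper mask networks can be configured via
    ``hidden``."""

    def __init__(self, d: int, rng: np.random.Generator,
                 hidden: int | None = None):
        super().__init__()
        if hidden:
            self.net = [Linear(d, hidden, rng), Linear(hidden, 1, rng)]
        else:
            self.net = [Linear(d, 1, rng)]

    def forward(self, tokens: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """tokens: (B, N, d) -> (S+, S-, M) with M (B, N, 1) in (0, 1)."""
        h = tokens
        for layer in self.net[:-1]:
            h = layer(h).relu()
        mask = self.net[-1](h).sigmoid()
        s_plus = tokens * mask
        s_minus = tokens * (1.0 - mask)
        return s_plus, s_minus, mask


class GlobalAggregator(Module):
    """Attention pooling of the decomposed sequence around a global token.

    Queries come from [global token; S+]; keys and values from [S+; S-].
    The global token's row is layer-normalized (residual) and passed through
    a residual feed-forward block to give g.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 ffn_dim: int | None = None):
        super().__init__()
        self.global_token = Tensor(
            rng.normal(0.0, 1.0, size=d).astype(np.float32),
            requires_grad=True)
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.norm = LayerNorm(d)
        self.ffn = FeedForward(d, ffn_dim or 2 * d, rng)

    def forward(self, s_plus: Tensor, s_minus: Tensor | None) -> Tensor:
        b = s_plus.shape[0]
        g0 = self.global_token.reshape(1, 1, -1) * Tensor(
            np.ones((b, 1, 1), dtype=np.float32))
        queries = concatenate([g0, s_plus], axis=1)
        keyvalue = (s_plus if s_minus is None
                    else concatenate([s_plus, s_minus], axis=1))
        attended = self.attn(queries, keyvalue)
        h = self.norm(queries + attended)[:, 0, :]  # global token row
        return h + self.ffn(h)

    @property
    def last_weights(self):
        return self.attn.last_weights


class RegressionHead(Module):
    """Three-layer progressively compressed MLP: C -> C/2 -> C/4 -> 1."""

    def __init__(self, d: int, rng: np.random.Generator,
                 dropout: float = 0.1,
                 hidden: tuple[int, int] | None = None):
        super().__init__()
        h1, h2 = hidden if hidden is not None else (max(d // 2, 1),
                                                    max(d // 4, 1))
        if not (d > h1 > h2 >= 1):
            raise ValueError("hidden dims must be strictly decreasing")
        self.fc1 = Linear(d, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.fc3 = Linear(h2, 1, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, g: Tensor) -> Tensor:
        u = self.drop1(self.fc1(g).relu())
        v = self.drop2(self.fc2(u).relu())
        return self.fc3(v).reshape(g.shape[0])


def robust_loss(pred: Tensor, target, eps: float = 1.0) -> Tensor:
    """Smooth-L1 objective: e^2/2 if |e| < eps else eps(|e| - eps/2)."""
    if eps <= 0:
        raise ValueError("robust-loss threshold eps must be > 0")
    target = target if isinstance(target, Tensor) else Tensor(
        np.asarray(target))
    err = pred - target
    abs_err = err.abs()
    quad = err * err * 0.5
    lin = abs_err * eps - 0.5 * eps ** 2
    return where(abs_err.data < eps, quad, lin).mean()


def mse_loss(pred: Tensor, target) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(
        np.asarray(target))
    err = pred - target
    return (err * err).mean()


def lipschitz_bound(head: RegressionHead,
                    activation_lipschitz: float = 1.0) -> float:
    """Product of layer operator (spectral) norms times the activation
    Lipschitz constants: an upper bound on the head's Lipschitz constant."""
    kappa = 1.0
    for layer in (head.fc1, head.fc2, head.fc3):
        kappa *= float(np.linalg.norm(layer.weight.data, ord=2))
    return kappa * activation_lipschitz ** 2


def lipschitz_probe(head: RegressionHead, n_pairs: int,
                    rng: np.random.Generator, scale: float = 1.0) -> dict:
    """Empirical |f(g) - f(g~)| / |g - g~| over random pairs vs the bound."""
    head.eval()
    d = head.fc1.weight.shape[0]
    from .nn import no_grad
    with no_grad():
        g1 = rng.normal(0, scale, size=(n_pairs, d)).astype(np.float32)
        g2 = rng.normal(0, scale, size=(n_pairs, d)).astype(np.float32)
        f1 = head(Tensor(g1)).data
        f2 = head(Tensor(g2)).data
    ratios = np.abs(f1 - f2) / np.linalg.norm(g1 - g2, axis=1)
    kappa = lipschitz_bound(head)
    return {"kappa_bound": kappa, "max_ratio": float(ratios.max()),
            "ratios": ratios, "all_within_bound": bool(
            np.all(ratios <= kappa + 1e-9))}
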