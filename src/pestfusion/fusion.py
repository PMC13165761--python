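"""Cross-modal alignment and environment-aware feature enhancement.

Alignment: visual tokens query the concatenated environmental and trap
tokens through multi-head scaled dot-product attention, followed by a
residual connection and layer normalization.  A first-order alignment loss
pulls the three per-sample modality means together in the shared space.

Enhancement: the raw environmental window is summarized into a context
vector by a projection + two temporal conv blocks; the context generates a
sigmoid channel gate ``a`` in (0,1) and a channel bias ``b`` applied to the
visual feature map as ``F * (1 + a) + b`` (conditional affine modulation),
after which a 1x1-conv sigmoid spatial map reweights positions.  Because
``a`` is bounded, the Frobenius norm of the modulated map obeys
``|F~| <= (1 + max a) |F| + sqrt(H W) |b|`` — verified as a property test.
"""

from __future__ import annotations

import numpy as np

from .nn import (Conv1d, Conv2d, LayerNorm, Linear, Module,
                 MultiHeadAttention, Tensor, concatenate)

__all__ = ["CrossModalAlign", "alignment_loss", "EnvContextEncoder",
           "ChannelModulator", "SpatialGate", "EnvAwareEnhancer",
           "modulation_norm_bound"]


class CrossModalAlign(Module):
    """Multi-head cross-attention with the visual tokens as queries."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 scaled: bool = True):
        super().__init__()
        self.attn = MultiHeadAttention(d, n_heads, rng, scaled=scaled)
        self.norm = LayerNorm(d)

    def forward(self, vis_tokens: Tensor, env_tokens: Tensor | None,
                trap_tokens: Tensor | None) -> Tensor:
        kv = [t for t in (env_tokens, trap_tokens) if t is not None]
        if not kv:
            raise ValueError("cross-modal alignment needs at least one "
                             "non-visual token set")
        keyvalue = kv[0] if len(kv) == 1 else concatenate(kv, axis=1)
        return self.norm(vis_tokens + self.attn(vis_tokens, keyvalue))

    @property
    def last_weights(self):
        return self.attn.last_weights


def alignment_loss(vis_tokens: Tensor, env_tokens: Tensor | None,
                   trap_tokens: Tensor | None) -> Tensor:
    """Squared distance between per-sample modality means, summed over the
    available non-visual modalities and averaged over the batch."""
    mu_v = vis_tokens.mean(axis=1)  # (B, d)
    total = None
    for other in (env_tokens, trap_tokens):
        if other is None:
            continue
        diff = mu_v - other.mean(axis=1)
        term = (diff * diff).sum(axis=-1)
        total = term if total is None else total + term
    if total is None:
        return Tensor(np.zeros(()))
    return total.mean()


class EnvContextEncoder(Module):
    """Projection + two temporal conv blocks -> temporal-mean context vector.

    Normalization inside each block is per-timestep over channels (layer
    style): batch-size independent and exactly deterministic at inference.
    """

    def __init__(self, n_vars: int, channels: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.project = Linear(n_vars, channels, rng)
        self.conv1 = Conv1d(channels, channels, kernel, rng, padding=kernel // 2)
        self.norm1 = LayerNorm(channels)
        self.conv2 = Conv1d(channels, channels, kernel, rng, padding=kernel // 2)
        self.norm2 = LayerNorm(channels)

    def forward(self, env: Tensor) -> tuple[Tensor, Tensor]:
        """env: (B, L, D) -> (U, z) with U (B, L, C) and z (B, C)."""
        if env.shape[1] < self.conv1.weight.shape[2]:
            raise ValueError("window shorter than the temporal kernel")
        u = self.project(env)                       # (B, L, C)
        u = u.swapaxes(1, 2)                        # (B, C, L)
        u = self.norm1(self.conv1(u).swapaxes(1, 2)).relu().swapaxes(1, 2)
        u = self.norm2(self.conv2(u).swapaxes(1, 2)).relu()
        z = u.mean(axis=1)                          # (B, C)
        return u, z


class ChannelModulator(Module):
    """Conditional affine modulation of a feature map by a context vector.

    gate a = sigmoid(W_a z + b_a) in (0,1); bias b = W_b z + b_b;
    output F * (1 + a) + b with channel vectors broadcast over space.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.gate = Linear(channels, channels, rng)
        self.bias = Linear(channels, channels, rng)

    def forward(self, feature_map: Tensor, z: Tensor
                ) -> tuple[Tensor, Tensor, Tensor]:
        """feature_map: (B, C, H, W); z: (B, C).  Returns (F~, a, b)."""
        if feature_map.shape[1] != z.shape[-1]:
            raise ValueError(
                f"channel mismatch: map has {feature_map.shape[1]}, "
                f"context has {z.shape[-1]}")
        a = self.gate(z).sigmoid()
        b = self.bias(z)
        a4 = a.reshape(a.shape[0], a.shape[1], 1, 1)
        b4 = b.reshape(b.shape[0], b.shape[1], 1, 1)
        return feature_map * (1.0 + a4) + b4, a, b


class SpatialGate(Module):
    """1x1-conv single-channel sigmoid map reweighting spatial positions."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, 1, 1, rng)

    def forward(self, feature_map: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (F_e, M_s); M_s has shape (B, 1, H, W), entries in (0,1)."""
        gate = self.conv(feature_map).sigmoid()
        return feature_map * gate, gate


class EnvAwareEnhancer(Module):
    """Context encoding + channel modulation + spatial reweighting."""

    def __init__(self, n_vars: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.context = EnvContextEncoder(n_vars, channels, rng)
        self.modulator = ChannelModulator(channels, rng)
        self.spatial = SpatialGate(channels, rng)
        self.last_gate: np.ndarray | None = None

    def forward(self, feature_map: Tensor, env: Tensor) -> Tensor:
        _, z = self.context(env)
        modulated, _, _ = self.modulator(feature_map, z)
        enhanced, gate = self.spatial(modulated)
        self.last_gate = gate.data
        return enhanced


def modulation_norm_bound(feature_map: np.ndarray, a: np.ndarray,
                          b: np.ndarray) -> float:
    """Upper bound (1 + |a|_inf) |F|_F + sqrt(H W) |b|_2 for one sample."""
    h, w = feature_map.shape[-2:]
    return ((1.0 + np.max(np.abs(a))) * np.linalg.norm(feature_map)
            + np.sqrt(h * w) * np.linalg.norm(b))
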