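"""Per-modality encoders into the shared d-dimensional token space.

* image patch  -> compact strided conv backbone -> spatial feature map F_v
                  -> flattened positions projected to d (visual tokens)
* env window   -> per-timestep linear projection + sinusoidal positions
* trap counts  -> per-visit affine lift + nonlinearity

The convolutional backbone is deliberately small (three stride-2 stages,
configurable width) so the full pipeline trains on a single CPU; the width
and depth are configuration, not architecture commitments.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor

__all__ = ["ConvEncoder", "EnvTokenEncoder", "TrapEmbedding",
           "SharedProjection", "sinusoidal_positions"]


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    """Standard fixed sine/cosine position table, shape (length, d)."""
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(np.float32)


class SharedProjection(Linear):
    """Affine map of a token set into the shared embedding dimension."""


class ConvEncoder(Module):
    """Three stride-2 conv stages; widths (w, 2w, 4w); ReLU between stages.

    For a P x P input the feature map is (P/8) x (P/8) with 4w channels.
    ``forward`` returns ``(feature_map, tokens)`` where the tokens are the
    row-major flattened spatial positions projected to ``d``.
    """

    def __init__(self, in_channels: int, width: int, d: int,
                 rng: np.random.Generator):
        super().__init__()
        self.width = width
        self.out_channels = 4 * width
        self.conv1 = Conv2d(in_channels, width, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(width, 2 * width, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(2 * width, 4 * width, 3, rng, stride=2, padding=1)
        self.project = SharedProjection(self.out_channels, d, rng)

    def forward(self, images: Tensor) -> tuple[Tensor, Tensor]:
        """images: (B, C, P, P) standardized pixels."""
        f = self.conv1(images).relu()
        f = self.conv2(f).relu()
        f = self.conv3(f).relu()
        b, c, h, w = f.shape
        tokens = self.project(
            f.transpose(0, 2, 3, 1).reshape(b, h * w, c))
        return f, tokens


class EnvTokenEncoder(Module):
    """Timestep-wise projection to d plus additive sinusoidal positions."""

    def __init__(self, n_vars: int, d: int, window_len: int,
                 rng: np.random.Generator):
        super().__init__()
        self.project = SharedProjection(n_vars, d, rng)
        self.positions = Tensor(sinusoidal_positions(window_len, d))

    def forward(self, env: Tensor) -> Tensor:
        """env: (B, L, D) standardized window -> (B, L, d) tokens."""
        if env.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"window length {env.shape[1]} does not match the "
                f"configured {self.positions.shape[0]}")
        return self.project(env) + self.positions


class TrapEmbedding(Module):
    """Per-visit scalar count lifted to d by an affine map + ReLU.

    Identical counts at two visits map to identical token rows (no
    positional term by default; inspection visits are exchangeable)."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.lift = Linear(1, d, rng)
        self.project = SharedProjection(d, d, rng)

    def forward(self, counts: Tensor) -> Tensor:
        """counts: (B, M) smoothed, scaled counts -> (B, M, d) tokens."""
        b, m = counts.shape
        if m < 1:
            raise ValueError("trap count sequence must be non-empty")
        return self.project(self.lift(counts.reshape(b, m, 1)).relu())
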