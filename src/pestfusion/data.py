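"""Core data containers for multimodal field samples.

A *sample* is one aligned training unit: a canopy image patch, a window of
environmental sensor readings, a short sequence of pheromone-trap counts,
and a scalar ground-truth pest density (individuals per m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EnvSeries", "MultimodalSample", "MultimodalDataset"]


@dataclass
class EnvSeries:
    """Timestamped multi-variable sensor record with a missingness mask.

    Attributes
    ----------
    times : (L,) float array, minutes, strictly increasing.
    values : (L, D) float array; entries at unobserved positions are NaN.
    mask : (L, D) bool array; True where the value was observed.
    names : the D variable names, in column order.
    """

    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (L, D) array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times length must match values rows")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must match number of variables")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "EnvSeries":
        return EnvSeries(self.times.copy(), self.values.copy(),
                         self.mask.copy(), tuple(self.names))


@dataclass
class MultimodalSample:
    """One aligned observation unit with its generative latents (if known)."""

    image: np.ndarray            # (P, P, 3) floats in [0, 1]
    env: EnvSeries               # (L, D) sensor window
    trap_counts: np.ndarray      # (M,) non-negative integer counts per visit
    density: float               # individuals per m^2, >= 0
    latent: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.trap_counts = np.asarray(self.trap_counts)
        if self.density < 0:
            raise ValueError("density label must be non-negative")
        if self.image.min() < -1e-9 or self.image.max() > 1 + 1e-9:
            raise ValueError("image values must lie in [0, 1]")
        if np.any(self.trap_counts < 0):
            raise ValueError("trap counts must be non-negative")


class MultimodalDataset:
    """Column-stacked view of a list of samples, convenient for batching."""

    def __init__(self, images: np.ndarray, env_times: np.ndarray,
                 env_values: np.ndarray, env_mask: np.ndarray,
                 env_names: tuple[str, ...], trap_counts: np.ndarray,
                 density: np.ndarray, latent: pd.DataFrame | None = None):
        self.images = np.asarray(images)          # (N, P, P, 3)
        self.env_times = np.asarray(env_times)    # (N, L) per-sample grid
        self.env_values = np.asarray(env_values)  # (N, L, D)
        self.env_mask = np.asarray(env_mask)      # (N, L, D)
        self.env_names = tuple(env_names)
        self.trap_counts = np.asarray(trap_counts)  # (N, M)
        self.density = np.asarray(density, dtype=float)  # (N,)
        n = len(self.density)
        self.latent = latent if latent is not None else pd.DataFrame(
            index=range(n))
        if not (len(self.images) == len(self.env_values)
                == len(self.trap_counts) == n):
            raise ValueError("modalities disagree on sample count")

    @classmethod
    def from_samples(cls, samples: list[MultimodalSample]) -> "MultimodalDataset":
        if not samples:
            raise ValueError("cannot build a dataset from zero samples")
        first = samples[0].env
        return cls(
            images=np.stack([s.image for s in samples]),
            env_times=np.stack([s.env.times for s in samples]),
            env_values=np.stack([s.env.values for s in samples]),
            env_mask=np.stack([s.env.mask for s in samples]),
            env_names=first.names,
            trap_counts=np.stack([s.trap_counts for s in samples]),
            density=np.array([s.density for s in samples]),
            latent=pd.DataFrame([s.latent for s in samples]),
        )

    def __len__(self) -> int:
        return len(self.density)

    def subset(self, idx) -> "MultimodalDataset":
        idx = np.asarray(idx)
        return MultimodalDataset(
            self.images[idx], self.env_times[idx], self.env_values[idx],
            self.env_mask[idx], self.env_names, self.trap_counts[idx],
            self.density[idx], self.latent.iloc[idx].reset_index(drop=True))

    def sample(self, i: int) -> MultimodalSample:
        env = EnvSeries(self.env_times[i], self.env_values[i],
                        self.env_mask[i], self.env_names)
        return MultimodalSample(self.images[i], env, self.trap_counts[i],
                                float(self.density[i]),
                                dict(self.latent.iloc[i]) if len(self.latent.columns) else {})
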