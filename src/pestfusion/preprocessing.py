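"""Deterministic preprocessing for the three modalities.

Images: sliding-window cropping, global standardization, and the geometric /
photometric augmentations (rotation, mirroring, linear brightness-contrast).
Environmental series: linear interpolation onto a target grid,
neighborhood-mean imputation of missing entries, per-variable
standardization.  Trap counts: centered moving-average smoothing and the
count -> density conversion through the effective attraction area of a trap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .data import EnvSeries

__all__ = [
    "crop_patches", "standardize_image", "unstandardize_image",
    "rotate_point", "rotate_image", "flip_image", "adjust_brightness",
    "AugmentationPolicy", "apply_augmentation",
    "interpolate_series", "impute_missing", "standardize_series",
    "smooth_counts", "counts_to_density",
    "NormStats", "compute_image_stats", "compute_series_stats",
    "UnresolvedGapError",
]


class UnresolvedGapError(ValueError):
    """A missing value had no observed neighbor inside the window."""

    def __init__(self, timestamps):
        self.timestamps = list(timestamps)
        super().__init__(
            "no observed neighbors within the imputation window at "
            f"timestamps {self.timestamps}")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def crop_patches(image: np.ndarray, h: int, w: int, stride: int = 1
                 ) -> np.ndarray:
    """All h x w sliding-window patches of ``image``, row-major order.

    Returns an array of shape (n_patches, h, w[, C]).  The patch count is
    ``floor((H-h)/stride + 1) * floor((W-w)/stride + 1)``.
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    if h > H or w > W:
        raise ValueError(f"crop window ({h}x{w}) larger than image ({H}x{W})")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    windows = np.lib.stride_tricks.sliding_window_view(
        image, (h, w), axis=(0, 1))[::stride, ::stride]
    n_rows, n_cols = windows.shape[:2]
    if image.ndim == 3:
        # sliding_window_view puts the window axes last
        windows = windows.transpose(0, 1, 3, 4, 2)
        return windows.reshape(n_rows * n_cols, h, w, image.shape[2]).copy()
    return windows.reshape(n_rows * n_cols, h, w).copy()


def standardize_image(image: np.ndarray, mu: float, sigma: float
                      ) -> np.ndarray:
    """Center and scale pixel values: ``(X - mu) / sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    return (np.asarray(image, dtype=float) - mu) / sigma


def unstandardize_image(image: np.ndarray, mu: float, sigma: float
                        ) -> np.ndarray:
    return np.asarray(image, dtype=float) * sigma + mu


def rotate_point(xy, theta: float) -> np.ndarray:
    """Rotate 2-D point(s) counterclockwise by ``theta`` radians about 0."""
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return (rot @ np.asarray(xy, dtype=float).T).T


def rotate_image(image: np.ndarray, theta: float) -> np.ndarray:
    """Rotate a raster patch counterclockwise by ``theta`` radians about its
    center.

    Exact multiples of 90 degrees use a lossless index permutation; other
    angles use bilinear resampling with reflected edges.
    """
    image = np.asarray(image, dtype=float)
    quarter = theta / (np.pi / 2.0)
    if abs(quarter - round(quarter)) < 1e-12:
        return np.rot90(image, k=int(round(quarter)) % 4, axes=(0, 1)).copy()
    return scipy.ndimage.rotate(image, np.degrees(theta), axes=(1, 0),
                                reshape=False, order=1, mode="reflect")


def flip_image(image: np.ndarray, horizontal: bool = False,
               vertical: bool = False) -> np.ndarray:
    out = np.asarray(image)
    if horizontal:
        out = out[:, ::-1]
    if vertical:
        out = out[::-1, :]
    return out.copy()


def adjust_brightness(image: np.ndarray, alpha: float, beta: float,
                      clip_range: tuple[float, float] = (0.0, 1.0)
                      ) -> np.ndarray:
    """Linear brightness-contrast transform ``alpha * X + beta``, clipped."""
    if alpha <= 0:
        raise ValueError("contrast factor alpha must be > 0")
    return np.clip(np.asarray(image, dtype=float) * alpha + beta,
                   clip_range[0], clip_range[1])


@dataclass
class AugmentationPolicy:
    """Stochastic augmentation sampler over rotations, flips and brightness.

    Each transform fires independently with its configured probability;
    continuous parameters are drawn uniformly from the stated ranges.  With
    all probabilities zero the policy is the identity.
    """

    p_rotate: float = 0.5
    theta_range: tuple[float, float] = (-np.pi, np.pi)
    p_flip_horizontal: float = 0.5
    p_flip_vertical: float = 0.5
    p_brightness: float = 0.5
    alpha_range: tuple[float, float] = (0.8, 1.2)
    beta_range: tuple[float, float] = (-0.1, 0.1)

    def __post_init__(self):
        for p in (self.p_rotate, self.p_flip_horizontal, self.p_flip_vertical,
                  self.p_brightness):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.alpha_range[0] <= 0:
            raise ValueError("contrast factors must be > 0")


def apply_augmentation(image: np.ndarray, policy: AugmentationPolicy,
                       rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(image, dtype=float)
    if rng.random() < policy.p_rotate:
        out = rotate_image(out, rng.uniform(*policy.theta_range))
    out = flip_image(out,
                     horizontal=rng.random() < policy.p_flip_horizontal,
                     vertical=rng.random() < policy.p_flip_vertical)
    if rng.random() < policy.p_brightness:
        out = adjust_brightness(out, rng.uniform(*policy.alpha_range),
                                rng.uniform(*policy.beta_range))
    return out


# ---------------------------------------------------------------------------
# environmental series
# ---------------------------------------------------------------------------

def interpolate_series(series: EnvSeries, target_times) -> EnvSeries:
    """Linearly interpolate every variable onto ``target_times``.

    Values at knots are preserved exactly; between two consecutive knots the
    value is the convex combination weighted by the fractional position of
    the target time.  Targets outside ``[t_1, t_N]`` raise rather than
    silently extrapolate.  The series must be fully observed (impute first).
    """
    target_times = np.asarray(target_times, dtype=float)
    if not series.mask.all():
        raise ValueError("interpolation requires a fully observed series; "
                         "impute missing values first")
    t = series.times
    if target_times.min() < t[0] or target_times.max() > t[-1]:
        raise ValueError("target times outside the observed range "
                         f"[{t[0]}, {t[-1]}]; extrapolation is not supported")
    out = np.column_stack([np.interp(target_times, t, series.values[:, j])
                           for j in range(series.n_vars)])
    return EnvSeries(target_times, out,
                     np.ones_like(out, dtype=bool), series.names)


def impute_missing(series: EnvSeries, delta: float) -> EnvSeries:
    """Replace each missing entry by the mean of observed values of the same
    variable within ``+/- delta`` minutes (closed window, excluding itself).

    Raises :class:`UnresolvedGapError` listing the offending timestamps if
    any missing entry has an empty neighborhood.
    """
    if delta <= 0:
        raise ValueError("imputation window delta must be > 0")
    out = series.values.copy()
    t = series.times
    unresolved: list[float] = []
    for j in range(series.n_vars):
        observed = series.mask[:, j]
        missing_idx = np.flatnonzero(~observed)
        if missing_idx.size == 0:
            continue
        obs_idx = np.flatnonzero(observed)
        for i in missing_idx:
            if obs_idx.size:
                near = obs_idx[np.abs(t[obs_idx] - t[i]) <= delta]
            else:
                near = obs_idx
            if near.size == 0:
                unresolved.append(float(t[i]))
            else:
                out[i, j] = series.values[near, j].mean()
    if unresolved:
        raise UnresolvedGapError(sorted(set(unresolved)))
    return EnvSeries(t.copy(), out, np.ones_like(out, dtype=bool),
                     series.names)


def standardize_series(series: EnvSeries, mu: np.ndarray, sigma: np.ndarray
                       ) -> EnvSeries:
    """Per-variable standardization ``(E - mu_E) / sigma_E``."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    bad = np.flatnonzero(sigma <= 0)
    if bad.size:
        names = [series.names[j] for j in bad]
        raise ValueError(f"zero or negative standard deviation for "
                         f"variable(s) {names}")
    out = (series.values - mu) / sigma
    return EnvSeries(series.times.copy(), out, series.mask.copy(),
                     series.names)


# ---------------------------------------------------------------------------
# trap counts
# ---------------------------------------------------------------------------

def smooth_counts(counts: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with window radius ``k``.

    Interior points average their 2k+1 neighbors; near the boundary the
    window shrinks symmetrically to the available neighbors, so the output
    has the same length as the input and every value is a true mean.
    """
    counts = np.asarray(counts, dtype=float)
    if k < 0:
        raise ValueError("window radius k must be >= 0")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if k == 0:
        return counts.copy()
    n = counts.shape[0]
    kernel = np.ones(2 * k + 1)
    sums = np.convolve(counts, kernel, mode="same")
    norm = np.convolve(np.ones(n), kernel, mode="same")
    return sums / norm


def counts_to_density(count, effective_area: float):
    """Convert a trap count to individuals per m^2 via the effective
    pheromone attraction area."""
    if effective_area <= 0:
        raise ValueError("effective attraction area must be > 0")
    return np.asarray(count, dtype=float) / effective_area


# ---------------------------------------------------------------------------
# normalization statistics
# ---------------------------------------------------------------------------

@dataclass
class NormStats:
    """Frozen standardization statistics, fit on the training split only."""

    image_mu: float = 0.0
    image_sigma: float = 1.0
    env_mu: np.ndarray = field(default_factory=lambda: np.zeros(1))
    env_sigma: np.ndarray = field(default_factory=lambda: np.ones(1))
    trap_mu: float = 0.0
    trap_sigma: float = 1.0

    def to_dict(self) -> dict:
        return {
            "image_mu": float(self.image_mu),
            "image_sigma": float(self.image_sigma),
            "env_mu": np.asarray(self.env_mu).tolist(),
            "env_sigma": np.asarray(self.env_sigma).tolist(),
            "trap_mu": float(self.trap_mu),
            "trap_sigma": float(self.trap_sigma),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(d["image_mu"], d["image_sigma"], np.asarray(d["env_mu"]),
                   np.asarray(d["env_sigma"]), d["trap_mu"], d["trap_sigma"])


def compute_image_stats(images: np.ndarray) -> tuple[float, float]:
    """Global pixel mean and standard deviation over a stack of images."""
    images = np.asarray(images, dtype=float)
    return float(images.mean()), float(images.std())


def compute_series_stats(values: np.ndarray, mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable mean/SD over a stack of windows (observed entries only).

    ``values`` has shape (N, L, D) or (L, D).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    flat = values.reshape(-1, values.shape[-1])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(-1, values.shape[-1])
        mu = np.array([flat[mask[:, j], j].mean()
                       for j in range(flat.shape[1])])
        sigma = np.array([flat[mask[:, j], j].std()
                          for j in range(flat.shape[1])])
    else:
        mu = flat.mean(axis=0)
        sigma = flat.std(axis=0)
    return mu, sigma
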