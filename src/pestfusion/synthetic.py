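"""Synthetic multimodal field-scene generator.

Every sample is produced by an explicit, documented generative law so that
each downstream stage (preprocessing, encoders, fusion, regression,
experiment harnesses) can be tested against known ground truth:

* a *density stratum* (low / medium / high, in individuals per trap) is
  drawn with the configured prevalences, and a per-trap rate ``lambda`` is
  drawn uniformly inside the stratum bounds;
* the scalar density label is ``y = lambda / effective_area`` (individuals
  per m^2);
* the canopy image shows elliptical damage blobs whose pixel fraction ``d``
  is chosen so that the latent density law
  ``y = (base + y_max * g(d)) * exp(sum_v c_v * z_v)`` holds exactly, where
  ``g`` is a normalized logistic in the damage fraction and ``z_v`` are the
  per-sample standardized environmental offsets (hydrothermal modifier);
* the environmental window is a diurnal sinusoid plus AR(1) noise per
  variable, shifted by the same offsets ``z_v``, with missing entries
  injected at the configured rate;
* trap counts are Poisson draws around ``y * effective_area`` scaled by a
  lognormal trap-efficiency factor — traps are an informative but imperfect
  proxy of the true density, in line with field practice where trap-derived
  and survey-derived densities correlate strongly but not perfectly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.special

from .data import EnvSeries, MultimodalDataset, MultimodalSample

__all__ = [
    "EnvVarSpec", "DensityLaw", "SceneConfig", "DEFAULT_ENV_SPECS",
    "latent_density_law", "inverse_damage_fraction", "render_damage_image",
    "simulate_env_series", "simulate_trap_counts", "generate_dataset",
    "write_dataset", "load_dataset",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EnvVarSpec:
    """Generative parameters of one environmental variable.

    value(t) = mean + offset_sd * z + diurnal_amp * sin(2*pi*t/1440 + phase)
               + AR(1) noise,  optionally clipped and with sparse bursts
               (used for rainfall).
    """

    mean: float
    diurnal_amp: float = 0.0
    phase: float = 0.0
    offset_sd: float = 0.0
    ar_sd: float = 0.0
    ar_rho: float = 0.8
    clip_min: float | None = None
    clip_max: float | None = None
    burst_rate: float = 0.0
    burst_scale: float = 0.0


def _default_env_specs() -> dict[str, EnvVarSpec]:
    return {
        "temperature": EnvVarSpec(mean=22.0, diurnal_amp=6.0, phase=-np.pi / 2,
                                  offset_sd=3.0, ar_sd=0.6),
        "humidity": EnvVarSpec(mean=60.0, diurnal_amp=15.0, phase=np.pi / 2,
                               offset_sd=8.0, ar_sd=2.0,
                               clip_min=0.0, clip_max=100.0),
        "wind_speed": EnvVarSpec(mean=3.0, diurnal_amp=1.0, offset_sd=1.0,
                                 ar_sd=0.5, clip_min=0.0),
        "rainfall": EnvVarSpec(mean=0.0, burst_rate=0.04, burst_scale=2.0,
                               clip_min=0.0),
        "illumination": EnvVarSpec(mean=25.0, diurnal_amp=25.0,
                                   phase=-np.pi / 2, offset_sd=5.0, ar_sd=2.0,
                                   clip_min=0.0),
    }


DEFAULT_ENV_SPECS = _default_env_specs()


@dataclass
class DensityLaw:
    """Deterministic smooth monotone map (damage, environment) -> density.

    ``y = (base_rate + y_max * g(d)) * exp(env_effect)`` with
    ``g(d) = (sigma(k(d - mid)) - sigma(-k*mid)) /
    (sigma(k(1 - mid)) - sigma(-k*mid))`` so that g(0)=0 and g(1)=1, strictly
    increasing.  ``base_rate`` (the density at zero damage under a neutral
    environment) is 0 by default: an undamaged field hosts no pests in this
    synthetic world.
    """

    y_max: float = 3.0
    k: float = 6.0
    mid: float = 0.45
    base_rate: float = 0.0

    def _g(self, d):
        lo = scipy.special.expit(-self.k * self.mid)
        hi = scipy.special.expit(self.k * (1.0 - self.mid))
        return (scipy.special.expit(self.k * (np.asarray(d, dtype=float)
                                              - self.mid)) - lo) / (hi - lo)

    def _g_inverse(self, g):
        lo = scipy.special.expit(-self.k * self.mid)
        hi = scipy.special.expit(self.k * (1.0 - self.mid))
        s = np.asarray(g, dtype=float) * (hi - lo) + lo
        return self.mid + scipy.special.logit(s) / self.k


@dataclass
class SceneConfig:
    """Study conditions of the synthetic benchmark."""

    patch_size: int = 64
    n_samples: int = 1000
    density_strata_probs: tuple[float, float, float] = (0.425, 0.358, 0.217)
    strata_bounds: tuple[float, float, float, float] = (0.0, 20.0, 50.0, 80.0)
    env_vars: tuple[str, ...] = ("temperature", "humidity", "wind_speed",
                                 "rainfall", "illumination")
    window_len: int = 48
    sensor_dt: float = 30.0          # minutes per step (field cadence 10-30)
    effective_area: float = 50.0     # m^2 attraction area per trap
    n_visits: int = 6                # trap inspections per sample window
    missing_rate: float = 0.05
    trap_noise_sigma: float = 0.3    # lognormal trap-efficiency spread
    env_effect_coeffs: dict[str, float] = field(
        default_factory=lambda: {"temperature": 0.30, "humidity": 0.18})
    env_specs: dict[str, EnvVarSpec] = field(default_factory=_default_env_specs)
    law: DensityLaw = field(default_factory=DensityLaw)
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.density_strata_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("density_strata_probs must be non-negative and "
                             "sum to 1 within 1e-9")
        if self.patch_size < 16:
            raise ValueError("patch_size must be >= 16")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.effective_area <= 0:
            raise ValueError("effective_area must be > 0")
        if np.any(np.diff(self.strata_bounds) <= 0):
            raise ValueError("strata_bounds must be strictly increasing")
        for name in self.env_vars:
            if name not in self.env_specs:
                raise ValueError(f"no generative spec for variable {name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# the latent law
# ---------------------------------------------------------------------------

def latent_density_law(damage_fraction, env_effect,
                       law: DensityLaw | None = None):
    """Density (individuals/m^2) implied by damage fraction and the summary
    environmental effect (log-scale hydrothermal modifier)."""
    law = law or DensityLaw()
    d = np.asarray(damage_fraction, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("damage_fraction must lie in [0, 1]")
    return (law.base_rate + law.y_max * law._g(d)) * np.exp(env_effect)


def inverse_damage_fraction(density, env_effect,
                            law: DensityLaw | None = None):
    """Damage fraction solving the latent law for a target density, or
    ``None`` when the target is unreachable for this environment."""
    law = law or DensityLaw()
    g = (np.asarray(density, dtype=float) / np.exp(env_effect)
         - law.base_rate) / law.y_max
    if np.any(g < 0) or np.any(g >= 1):
        return None
    d = law._g_inverse(np.clip(g, 0.0, 1.0 - 1e-12))
    return float(np.clip(d, 0.0, 1.0)) if np.ndim(density) == 0 else \
        np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# renderers / simulators
# ---------------------------------------------------------------------------

_CANOPY_RGB = np.array([0.16, 0.42, 0.14])
_DAMAGE_RGB = np.array([0.48, 0.36, 0.14])


def render_damage_image(damage_fraction: float, patch_size: int,
                        seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Procedural canopy patch with elliptical damage blobs.

    The blob field is thresholded at the exact pixel count implied by
    ``damage_fraction``, so the returned boolean mask doubles as a
    ground-truth oracle for the rendered damage area.

    Returns ``(image, mask)`` with image values in [0, 1].
    """
    if not 0.0 <= damage_fraction <= 1.0:
        raise ValueError("damage_fraction must lie in [0, 1]")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    p = int(patch_size)

    # textured canopy background
    tex = scipy.ndimage.gaussian_filter(rng.standard_normal((p, p)), sigma=2.0)
    tex = tex / (tex.std() + 1e-9)
    grain = 0.02 * rng.standard_normal((p, p, 3))
    image = (_CANOPY_RGB[None, None, :]
             + tex[:, :, None] * np.array([0.03, 0.06, 0.02]) + grain)

    n_pix = int(round(damage_fraction * p * p))
    mask = np.zeros((p, p), dtype=bool)
    if n_pix > 0:
        n_blobs = 1 + rng.poisson(2.0 + 8.0 * damage_fraction)
        yy, xx = np.mgrid[0:p, 0:p]
        fld = np.zeros((p, p))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, p, size=2)
            s1, s2 = rng.uniform(p / 16.0, p / 5.0, size=2)
            ang = rng.uniform(0, np.pi)
            ca, sa = np.cos(ang), np.sin(ang)
            u = (xx - cx) * ca + (yy - cy) * sa
            v = -(xx - cx) * sa + (yy - cy) * ca
            fld += np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))
        fld += 1e-9 * rng.standard_normal((p, p))  # tie break
        flat = np.argpartition(fld.ravel(), -n_pix)[-n_pix:]
        mask.ravel()[flat] = True
        dmg = (_DAMAGE_RGB[None, None, :]
               + 0.04 * rng.standard_normal((p, p, 3)))
        image = np.where(mask[:, :, None], dmg, image)
    return np.clip(image, 0.0, 1.0).astype(np.float32), mask


def simulate_env_series(config: SceneConfig, seed_or_rng,
                        offsets: dict[str, float] | None = None) -> EnvSeries:
    """One environmental sensor window under the configured per-variable
    generative specs.

    ``offsets`` are standardized per-sample baseline shifts ``z_v`` (drawn
    N(0,1) when not supplied); the same shifts feed the latent density law.
    Missing entries are injected uniformly at ``config.missing_rate`` and
    flagged in the mask (values set to NaN).
    """
    if config.window_len < 2:
        raise ValueError("window_len must be >= 2")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    L, dt = config.window_len, config.sensor_dt
    start = rng.uniform(0.0, 1440.0)
    times = start + dt * np.arange(L)
    values = np.empty((L, len(config.env_vars)))
    offsets = dict(offsets or {})
    for j, name in enumerate(config.env_vars):
        spec = config.env_specs[name]
        z = offsets.setdefault(name, float(rng.standard_normal()))
        base = (spec.mean + spec.offset_sd * z
                + spec.diurnal_amp * np.sin(2 * np.pi * times / 1440.0
                                            + spec.phase))
        noise = np.zeros(L)
        if spec.ar_sd > 0:
            innov = rng.normal(0.0, spec.ar_sd * np.sqrt(1 - spec.ar_rho ** 2),
                               size=L)
            noise[0] = rng.normal(0.0, spec.ar_sd)
            for t in range(1, L):
                noise[t] = spec.ar_rho * noise[t - 1] + innov[t]
        col = base + noise
        if spec.burst_rate > 0:
            bursts = rng.random(L) < spec.burst_rate
            col = col + bursts * rng.exponential(spec.burst_scale, size=L)
        if spec.clip_min is not None:
            col = np.maximum(col, spec.clip_min)
        if spec.clip_max is not None:
            col = np.minimum(col, spec.clip_max)
        values[:, j] = col
    mask = np.ones_like(values, dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) >= config.missing_rate
        values = np.where(mask, values, np.nan)
    return EnvSeries(times, values, mask, tuple(config.env_vars))


def simulate_trap_counts(density: float, effective_area: float,
                         n_visits: int, seed_or_rng) -> np.ndarray:
    """Independent Poisson trap counts with mean density * effective_area."""
    if density < 0:
        raise ValueError("density must be non-negative")
    if effective_area <= 0:
        raise ValueError("effective_area must be > 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.poisson(density * effective_area, size=int(n_visits))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SceneConfig) -> list[MultimodalSample]:
    """Draw ``config.n_samples`` internally consistent multimodal samples.

    Stratum-first sampling: the stratum is drawn with the configured
    prevalences, a per-trap rate uniformly inside the stratum bounds, and
    the damage fraction is solved from the latent law given the sample's
    environmental offsets (with rejection of the rare unreachable
    combinations at the top of the density range).
    """
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.density_strata_probs, dtype=float)
    bounds = np.asarray(config.strata_bounds, dtype=float)
    strata = rng.choice(len(probs), size=config.n_samples, p=probs)
    samples: list[MultimodalSample] = []
    for i in range(config.n_samples):
        s = int(strata[i])
        for _ in range(200):
            offsets = {name: float(rng.standard_normal())
                       for name in config.env_vars}
            env_effect = sum(c * offsets[v]
                             for v, c in config.env_effect_coeffs.items())
            lam = rng.uniform(bounds[s], bounds[s + 1])
            y = lam / config.effective_area
            d = inverse_damage_fraction(y, env_effect, config.law)
            if d is not None:
                break
        else:
            raise RuntimeError("could not find a feasible damage fraction; "
                               "check law / strata configuration")
        image, mask_img = render_damage_image(d, config.patch_size, rng)
        env = simulate_env_series(config, rng, offsets=offsets)
        eta = (rng.lognormal(-0.5 * config.trap_noise_sigma ** 2,
                             config.trap_noise_sigma)
               if config.trap_noise_sigma > 0 else 1.0)
        counts = simulate_trap_counts(y * eta, config.effective_area,
                                      config.n_visits, rng)
        samples.append(MultimodalSample(
            image=image, env=env, trap_counts=counts, density=y,
            latent={"damage_fraction": d, "env_effect": env_effect,
                    "stratum": s, "trap_rate": lam, "trap_efficiency": eta,
                    **{f"z_{k}": v for k, v in offsets.items()}}))
    return samples


# ---------------------------------------------------------------------------
# on-disk schema: PNG images + long-format CSVs + JSON manifest
# ---------------------------------------------------------------------------

def write_dataset(samples: list[MultimodalSample], outdir,
                  config: SceneConfig | None = None) -> None:
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    env_rows, trap_rows, label_rows = [], [], []
    for i, s in enumerate(samples):
        sid = f"{i:06d}"
        iio.imwrite(outdir / "images" / f"{sid}.png",
                    np.round(s.image * 255).astype(np.uint8))
        for t in range(s.env.n_steps):
            for j, name in enumerate(s.env.names):
                observed = bool(s.env.mask[t, j])
                env_rows.append((sid, t, s.env.times[t], name,
                                 s.env.values[t, j] if observed else np.nan,
                                 int(observed)))
        for v, c in enumerate(s.trap_counts):
            trap_rows.append((sid, v, int(c)))
        label_rows.append((sid, s.density, s.latent.get("stratum", -1),
                           s.latent.get("damage_fraction", np.nan)))
    pd.DataFrame(env_rows, columns=["sample_id", "t_index",
                                    "timestamp_minutes", "var_name", "value",
                                    "observed_flag"]).to_csv(
        outdir / "env.csv", index=False)
    pd.DataFrame(trap_rows, columns=["sample_id", "visit_index", "count"]
                 ).to_csv(outdir / "traps.csv", index=False)
    pd.DataFrame(label_rows, columns=["sample_id", "density", "stratum",
                                      "damage_fraction"]).to_csv(
        outdir / "labels.csv", index=False)
    manifest = {
        "n_samples": len(samples),
        "files": ["env.csv", "traps.csv", "labels.csv"]
                 + [f"images/{i:06d}.png" for i in range(len(samples))],
    }
    if config is not None:
        cfg = config.to_dict()
        cfg["env_specs"] = {k: dataclasses.asdict(v)
                            for k, v in config.env_specs.items()}
        manifest["config"] = cfg
        manifest["seed"] = config.seed
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)


def load_dataset(outdir) -> MultimodalDataset:
    outdir = Path(outdir)
    labels = pd.read_csv(outdir / "labels.csv",
                         dtype={"sample_id": str}).set_index("sample_id")
    env = pd.read_csv(outdir / "env.csv", dtype={"sample_id": str})
    traps = pd.read_csv(outdir / "traps.csv", dtype={"sample_id": str})
    names = tuple(env.loc[env.sample_id == env.sample_id.iloc[0], "var_name"]
                  .unique())
    samples = []
    for sid, row in labels.iterrows():
        image = iio.imread(outdir / "images" / f"{sid}.png") / 255.0
        e = env[env.sample_id == sid]
        piv_v = e.pivot(index="t_index", columns="var_name", values="value")
        piv_m = e.pivot(index="t_index", columns="var_name",
                        values="observed_flag").astype(bool)
        tgrid = e.groupby("t_index")["timestamp_minutes"].first().values
        series = EnvSeries(tgrid, piv_v[list(names)].values,
                           piv_m[list(names)].values, names)
        counts = traps.loc[traps.sample_id == sid].sort_values("visit_index")[
            "count"].values
        samples.append(MultimodalSample(
            image=image, env=series, trap_counts=counts,
            density=float(row.density),
            latent={"stratum": int(row.stratum),
                    "damage_fraction": float(row.damage_fraction)}))
    return MultimodalDataset.from_samples(samples)
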