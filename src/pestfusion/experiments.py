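"""Experiment harnesses: ablations, modality combinations, sensitivity.

All harnesses train variants from scratch on shared splits and seeds and
aggregate metric records across seeds by the arithmetic mean.  The
sensitivity harness uses permutation importance: one environmental
variable's windows are shuffled across test samples (distribution
preserving) while everything else is held fixed, and the increase in
prediction error attributes importance to that variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MultimodalDataset
from .metrics import MetricsRecord, evaluate
from .model import ModelConfig, PestDensityModel, PestDensityResults, TrainConfig
from .synthetic import SceneConfig, generate_dataset

__all__ = ["ABLATION_VARIANTS", "MODALITY_COMBOS", "ExperimentReport",
           "run_ablation", "run_modality_experiment", "sensitivity_analysis",
           "SensitivityReport", "run_recovery_benchmark"]


ABLATION_VARIANTS = {
    "full": {},
    "no_alignment": {"use_alignment": False},
    "no_env_aware": {"use_env_enhancer": False},
    "no_decomposition": {"use_decomposition": False},
    "image_only": {"modalities": ("image",), "use_alignment": False,
                   "use_env_enhancer": False},
}

MODALITY_COMBOS = {
    "image_only": ("image",),
    "env_only": ("env",),
    "trap_only": ("trap",),
    "image+env": ("image", "env"),
    "image+trap": ("image", "trap"),
    "env+trap": ("env", "trap"),
    "image+env+trap": ("image", "env", "trap"),
}


@dataclass
class ExperimentReport:
    """Per-variant result: per-seed metric records and their mean."""

    variant: str
    modalities: tuple[str, ...]
    per_seed: dict[int, MetricsRecord] = field(default_factory=dict)

    @property
    def mean_mae(self) -> float:
        return float(np.mean([m.mae for m in self.per_seed.values()]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([m.rmse for m in self.per_seed.values()]))

    @property
    def mean_r2(self) -> float:
        return float(np.mean([m.r2 for m in self.per_seed.values()]))

    def row(self) -> dict:
        return {"variant": self.variant,
                "modalities": "+".join(self.modalities),
                "mae": self.mean_mae, "rmse": self.mean_rmse,
                "r2": self.mean_r2,
                "mape": float(np.mean([m.mape
                                       for m in self.per_seed.values()])),
                "n_seeds": len(self.per_seed)}


def _train_variant(dataset: MultimodalDataset, base: ModelConfig,
                   overrides: dict, train_config: TrainConfig,
                   seed: int) -> PestDensityResults:
    cfg = replace(base, **overrides)
    return PestDensityModel(dataset, cfg).fit(train_config, seed=seed)


def run_ablation(dataset: MultimodalDataset, base_config: ModelConfig,
                 train_config: TrainConfig, seeds=(0,),
                 variants=None) -> dict[str, ExperimentReport]:
    """Train the full model and the structural-removal variants."""
    variants = variants or list(ABLATION_VARIANTS)
    reports: dict[str, ExperimentReport] = {}
    for name in variants:
        if name not in ABLATION_VARIANTS:
            raise KeyError(f"unknown ablation variant {name!r}")
        overrides = ABLATION_VARIANTS[name]
        report = ExperimentReport(
            name, overrides.get("modalities", base_config.modalities))
        for seed in seeds:
            res = _train_variant(dataset, base_config, overrides,
                                 train_config, seed)
            report.per_seed[seed] = res.metrics("test")
        reports[name] = report
    return reports


def run_modality_experiment(dataset: MultimodalDataset,
                            base_config: ModelConfig,
                            train_config: TrainConfig, seeds=(0,)
                            ) -> dict[str, ExperimentReport]:
    """Train all 7 modality configurations (3 single, 3 pairwise, 1 full).

    Absent modalities are structurally removed from the network, not
    zero-filled."""
    reports: dict[str, ExperimentReport] = {}
    for name, modalities in MODALITY_COMBOS.items():
        report = ExperimentReport(name, modalities)
        for seed in seeds:
            res = _train_variant(dataset, base_config,
                                 {"modalities": modalities}, train_config,
                                 seed)
            report.per_seed[seed] = res.metrics("test")
        reports[name] = report
    return reports


@dataclass
class SensitivityReport:
    """Per-factor error increases and normalized importance scores."""

    baseline: MetricsRecord
    delta_mae: dict[str, float]
    delta_rmse: dict[str, float]

    @property
    def importance(self) -> dict[str, float]:
        pos = {k: max(v, 0.0) for k, v in self.delta_mae.items()}
        total = sum(pos.values())
        if total <= 0:
            return {k: 1.0 / len(pos) for k in pos}
        return {k: v / total for k, v in pos.items()}

    def frame(self) -> pd.DataFrame:
        imp = self.importance
        return pd.DataFrame({
            "factor": list(self.delta_mae),
            "delta_mae": [self.delta_mae[k] for k in self.delta_mae],
            "delta_rmse": [self.delta_rmse[k] for k in self.delta_mae],
            "importance": [imp[k] for k in self.delta_mae],
        })


def sensitivity_analysis(results: PestDensityResults, factors=None,
                         split: str = "test", seed: int = 0
                         ) -> SensitivityReport:
    """Permutation importance of environmental factors on a fitted model."""
    names = list(results.model.dataset.env_names)
    factors = list(factors) if factors is not None else names
    unknown = set(factors) - set(names)
    if unknown:
        raise KeyError(f"unknown factor(s) {sorted(unknown)}")
    arrays = results.arrays[split]
    y = arrays["y"]
    baseline = evaluate(y, results.predict_arrays(arrays))
    rng = np.random.default_rng(seed)
    d_mae, d_rmse = {}, {}
    for factor in factors:
        j = names.index(factor)
        perm = rng.permutation(len(y))
        env = arrays["env"].copy()
        env[:, :, j] = env[perm][:, :, j]
        perturbed = dict(arrays, env=env)
        m = evaluate(y, results.predict_arrays(perturbed))
        d_mae[factor] = m.mae - baseline.mae
        d_rmse[factor] = m.rmse - baseline.rmse
    return SensitivityReport(baseline, d_mae, d_rmse)


# ---------------------------------------------------------------------------
# the scaled synthetic recovery benchmark
# ---------------------------------------------------------------------------

def benchmark_scene_config(seed: int, n_samples: int = 2000) -> SceneConfig:
    """Study conditions of the synthetic recovery benchmark."""
    return SceneConfig(n_samples=n_samples, patch_size=64, seed=seed)


def benchmark_train_config() -> TrainConfig:
    """Scaled-down optimization protocol for the CPU benchmark."""
    return TrainConfig(epochs=16, batch_size=64, learning_rate=2e-3,
                       lr_min=1e-4, patience=0)


def run_recovery_benchmark(seeds=(0, 1, 2), n_samples: int = 2000,
                           verbose: bool = False) -> dict:
    """End-to-end parameter recovery on the synthetic benchmark.

    For each seed: generate a dataset, train the full three-modality model
    and the image-only variant on shared splits, measure held-out metrics,
    and run the environmental sensitivity analysis on the full model.
    """
    cfg = ModelConfig()
    tc = benchmark_train_config()
    rows = []
    sens_frames = []
    for seed in seeds:
        dataset = MultimodalDataset.from_samples(
            generate_dataset(benchmark_scene_config(seed, n_samples)))
        full = PestDensityModel(dataset, cfg).fit(tc, seed=seed)
        image_only = PestDensityModel(
            dataset, replace(cfg, modalities=("image",),
                             use_alignment=False,
                             use_env_enhancer=False)).fit(tc, seed=seed)
        m_full = full.metrics("test")
        m_img = image_only.metrics("test")
        sens = sensitivity_analysis(full, seed=seed)
        sens_frames.append(sens.frame().assign(seed=seed))
        rows.append({"seed": seed, "full_mae": m_full.mae,
                     "full_rmse": m_full.rmse, "full_r2": m_full.r2,
                     "full_mape": m_full.mape,
                     "image_only_mae": m_img.mae,
                     "image_only_rmse": m_img.rmse,
                     "image_only_r2": m_img.r2})
        if verbose:
            print(f"seed {seed}: full {m_full} | image-only {m_img}")
    per_seed = pd.DataFrame(rows)
    sens_all = pd.concat(sens_frames, ignore_index=True)
    importance = sens_all.groupby("factor")["importance"].mean()
    return {
        "per_seed": per_seed,
        "sensitivity": sens_all,
        "summary": {
            "full_mae": float(per_seed.full_mae.mean()),
            "full_rmse": float(per_seed.full_rmse.mean()),
            "full_r2": float(per_seed.full_r2.mean()),
            "full_mape": float(per_seed.full_mape.mean()),
            "image_only_mae": float(per_seed.image_only_mae.mean()),
            "image_only_r2": float(per_seed.image_only_r2.mean()),
            "importance": importance.to_dict(),
            "n_samples": n_samples,
            "seeds": list(seeds),
        },
    }
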