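"""Model/Results interface for multimodal pest-density estimation.

:class:`PestDensityModel` is constructed from a :class:`MultimodalDataset`
and a :class:`ModelConfig`; :meth:`PestDensityModel.fit` runs the seeded
training protocol (Adam, cosine-annealed learning rate, early stopping on
the validation split) and returns a :class:`PestDensityResults` carrying
the fitted network, per-epoch history, held-out predictions and metrics,
and a ``summary()`` table.

The network follows a fixed inference pathway: each modality is encoded
into shared d-dimensional tokens; visual tokens query the concatenated
environmental/trap tokens (cross-modal alignment); the environmental window
conditions an affine channel modulation and spatial gate on the visual
feature map; the enhanced tokens plus the aligned tokens form the fused
sequence that the saliency-decomposed attention pool reduces to a global
representation, mapped to the scalar density by a compressing MLP.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MultimodalDataset
from .encoders import ConvEncoder, EnvTokenEncoder, TrapEmbedding
from .fusion import CrossModalAlign, EnvAwareEnhancer, alignment_loss
from .metrics import MetricsRecord, evaluate
from .nn import (Adam, Linear, Module, Tensor, concatenate,
                 cosine_annealing_lr, no_grad)
from .preprocessing import (NormStats, UnresolvedGapError,
                            compute_image_stats, compute_series_stats,
                            impute_missing, smooth_counts)
from .regression import (GlobalAggregator, RegressionHead,
                         SaliencyDecomposition, mse_loss, robust_loss)
from .data import EnvSeries

__all__ = ["ModelConfig", "TrainConfig", "Preprocessor",
           "PestDensityNetwork", "PestDensityModel", "PestDensityResults",
           "train_val_test_split", "kfold_indices"]

MODALITIES = ("image", "env", "trap")


@dataclass
class ModelConfig:
    """Architecture and objective configuration."""

    d: int = 32                  # shared embedding dimension
    conv_width: int = 8          # first-stage conv channels (C' = 4 * width)
    n_heads: int = 4             # attention heads (4 or 8 are sensible)
    ffn_dim: int = 64
    dropout: float = 0.1
    eps: float = 1.0             # robust-loss branch threshold
    loss: str = "robust"         # "robust" (default) or "mse"
    lambda_align: float = 0.1    # alignment-loss weight
    modalities: tuple[str, ...] = MODALITIES
    use_alignment: bool = True
    use_env_enhancer: bool = True
    use_decomposition: bool = True
    smoothing_k: int = 1         # trap moving-average radius (visits)

    def __post_init__(self):
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        if self.lambda_align < 0:
            raise ValueError("lambda_align must be >= 0")
        if self.loss not in ("robust", "mse"):
            raise ValueError("loss must be 'robust' or 'mse'")

    @property
    def feature_channels(self) -> int:
        return 4 * self.conv_width


@dataclass
class TrainConfig:
    """Optimization protocol (defaults follow the full field protocol; the
    scaled-down synthetic benchmark overrides epochs and learning rate)."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-4
    lr_min: float = 1e-6
    patience: int = 10
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def train_val_test_split(n: int, ratios, seed: int):
    """Seeded shuffled index split; returns (train, val, test) arrays."""
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def kfold_indices(n: int, k: int, seed: int):
    """Seeded k-fold partition; yields (train_idx, test_idx) pairs."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        yield train, test


class Preprocessor:
    """Freezes standardization statistics on the training split and maps a
    dataset to model-ready float32 arrays (impute -> standardize images,
    series; smooth -> standardize trap counts)."""

    def __init__(self, smoothing_k: int = 1, impute_delta: float | None = None):
        self.smoothing_k = smoothing_k
        self.impute_delta = impute_delta
        self.stats: NormStats | None = None

    def _imputed_env(self, ds: MultimodalDataset) -> np.ndarray:
        out = np.empty_like(ds.env_values)
        for i in range(len(ds)):
            if ds.env_mask[i].all():
                out[i] = ds.env_values[i]
                continue
            series = EnvSeries(ds.env_times[i], ds.env_values[i],
                               ds.env_mask[i], ds.env_names)
            dt = float(np.median(np.diff(ds.env_times[i])))
            delta = self.impute_delta or 3.0 * dt
            while True:
                try:
                    out[i] = impute_missing(series, delta).values
                    break
                except UnresolvedGapError:
                    # widen the neighborhood for pathological gap runs
                    delta *= 2.0
        return out

    def fit(self, train_ds: MultimodalDataset) -> "Preprocessor":
        env = self._imputed_env(train_ds)
        mu_i, sd_i = compute_image_stats(train_ds.images)
        mu_e, sd_e = compute_series_stats(env)
        smoothed = np.apply_along_axis(smooth_counts, 1,
                                       train_ds.trap_counts.astype(float),
                                       self.smoothing_k)
        self.stats = NormStats(image_mu=mu_i, image_sigma=max(sd_i, 1e-8),
                               env_mu=mu_e,
                               env_sigma=np.maximum(sd_e, 1e-8),
                               trap_mu=float(smoothed.mean()),
                               trap_sigma=max(float(smoothed.std()), 1e-8))
        return self

    def transform(self, ds: MultimodalDataset) -> dict[str, np.ndarray]:
        if self.stats is None:
            raise RuntimeError("preprocessor not fitted")
        st = self.stats
        images = ((ds.images - st.image_mu) / st.image_sigma).astype(
            np.float32).transpose(0, 3, 1, 2)
        env = ((self._imputed_env(ds) - st.env_mu) / st.env_sigma).astype(
            np.float32)
        smoothed = np.apply_along_axis(smooth_counts, 1,
                                       ds.trap_counts.astype(float),
                                       self.smoothing_k)
        traps = ((smoothed - st.trap_mu) / st.trap_sigma).astype(np.float32)
        return {"images": images, "env": env, "traps": traps,
                "y": ds.density.astype(np.float32)}


class PestDensityNetwork(Module):
    """The assembled multimodal network (see module docstring)."""

    def __init__(self, config: ModelConfig, n_env_vars: int, window_len: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config.feature_channels
        d = config.d
        self.use_image = "image" in config.modalities
        self.use_env = "env" in config.modalities
        self.use_trap = "trap" in config.modalities
        if self.use_image:
            self.image_encoder = ConvEncoder(3, config.conv_width, d, rng)
            self.enhanced_project = Linear(c, d, rng)
        if self.use_env:
            self.env_encoder = EnvTokenEncoder(n_env_vars, d, window_len, rng)
        if self.use_trap:
            self.trap_embedding = TrapEmbedding(d, rng)
        self.align_active = (config.use_alignment and self.use_image
                             and (self.use_env or self.use_trap))
        if self.align_active:
            self.cross_align = CrossModalAlign(d, config.n_heads, rng)
        self.enhancer_active = (config.use_env_enhancer and self.use_image
                                and self.use_env)
        if self.enhancer_active:
            self.enhancer = EnvAwareEnhancer(n_env_vars, c, rng)
        if config.use_decomposition:
            self.decomposition = SaliencyDecomposition(d, rng)
        self.aggregator = GlobalAggregator(d, config.n_heads, rng,
                                           ffn_dim=config.ffn_dim)
        self.head = RegressionHead(d, rng, dropout=config.dropout)

    def forward(self, batch: dict, return_align: bool = False):
        env_t = Tensor(batch["env"]) if self.use_env else None
        trap_t = Tensor(batch["traps"]) if self.use_trap else None
        env_tokens = self.env_encoder(env_t) if self.use_env else None
        trap_tokens = self.trap_embedding(trap_t) if self.use_trap else None

        align = None
        if self.use_image:
            images = Tensor(batch["images"])
            fmap, vis_tokens = self.image_encoder(images)
            if self.enhancer_active:
                fmap = self.enhancer(fmap, env_t)
            b, c, h, w = fmap.shape
            fused_tokens = self.enhanced_project(
                fmap.transpose(0, 2, 3, 1).reshape(b, h * w, c))
            if self.align_active:
                z_align = self.cross_align(vis_tokens, env_tokens,
                                           trap_tokens)
                tokens = fused_tokens + z_align
                align = alignment_loss(vis_tokens, env_tokens, trap_tokens)
            else:
                parts = [fused_tokens]
                if env_tokens is not None:
                    parts.append(env_tokens)
                if trap_tokens is not None:
                    parts.append(trap_tokens)
                tokens = (parts[0] if len(parts) == 1
                          else concatenate(parts, axis=1))
        else:
            parts = [t for t in (env_tokens, trap_tokens) if t is not None]
            tokens = parts[0] if len(parts) == 1 else concatenate(parts,
                                                                  axis=1)

        if self.config.use_decomposition:
            s_plus, s_minus, _ = self.decomposition(tokens)
        else:
            s_plus, s_minus = tokens, None
        g = self.aggregator(s_plus, s_minus)
        pred = self.head(g)
        if return_align:
            return pred, align
        return pred


def total_loss(prediction_loss, align_loss, lambda_align: float):
    """Composite objective L_d + lambda * L_align."""
    if lambda_align < 0:
        raise ValueError("lambda_align must be >= 0")
    if align_loss is None or lambda_align == 0:
        return prediction_loss
    return prediction_loss + lambda_align * align_loss


class PestDensityModel:
    """Multimodal pest-density regression model.

    Parameters
    ----------
    dataset : MultimodalDataset
        Aligned samples (images, environmental windows, trap counts,
        density labels).
    config : ModelConfig, optional
        Architecture / objective configuration.
    """

    def __init__(self, dataset: MultimodalDataset,
                 config: ModelConfig | None = None):
        self.dataset = dataset
        self.config = config or ModelConfig()

    @classmethod
    def from_samples(cls, samples, config: ModelConfig | None = None):
        return cls(MultimodalDataset.from_samples(samples), config)

    def fit(self, train_config: TrainConfig | None = None, seed: int = 0,
            verbose: bool = False) -> "PestDensityResults":
        cfg = self.config
        tc = train_config or TrainConfig()
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(4)]
        idx_train, idx_val, idx_test = train_val_test_split(
            len(self.dataset), tc.split, seeds[0])

        pre = Preprocessor(smoothing_k=cfg.smoothing_k)
        pre.fit(self.dataset.subset(idx_train))
        arr = {name: pre.transform(self.dataset.subset(idx))
               for name, idx in (("train", idx_train), ("val", idx_val),
                                 ("test", idx_test))}

        init_rng = np.random.default_rng(seeds[1])
        net = PestDensityNetwork(cfg, len(self.dataset.env_names),
                                 self.dataset.env_values.shape[1], init_rng)
        # reseed dropout streams deterministically
        drop_rng = np.random.default_rng(seeds[2])
        net.head.drop1.rng = drop_rng
        net.head.drop2.rng = drop_rng
        shuffle_rng = np.random.default_rng(seeds[3])

        opt = Adam(net.parameters(), lr=tc.learning_rate)
        pred_loss = (lambda p, y: robust_loss(p, y, cfg.eps)) \
            if cfg.loss == "robust" else mse_loss

        def run_loss(split_arrays, batch_size) -> float:
            net.eval()
            losses, weights = [], []
            with no_grad():
                for lo in range(0, len(split_arrays["y"]), batch_size):
                    batch = {k: v[lo:lo + batch_size]
                             for k, v in split_arrays.items()}
                    p = net(batch)
                    losses.append(pred_loss(p, batch["y"]).item())
                    weights.append(len(batch["y"]))
            return float(np.average(losses, weights=weights))

        history = []
        best_val = np.inf
        best_state = net.state_dict()
        best_epoch = -1
        n_train = len(arr["train"]["y"])
        for epoch in range(tc.epochs):
            lr = cosine_annealing_lr(epoch, tc.learning_rate, tc.epochs,
                                     tc.lr_min)
            opt.lr = lr
            order = (shuffle_rng.permutation(n_train)
                     if tc.shuffle_each_epoch else np.arange(n_train))
            net.train()
            epoch_losses, epoch_w = [], []
            for lo in range(0, n_train, tc.batch_size):
                sel = order[lo:lo + tc.batch_size]
                batch = {k: v[sel] for k, v in arr["train"].items()}
                pred, align = net(batch, return_align=True)
                loss = total_loss(pred_loss(pred, batch["y"]), align,
                                  cfg.lambda_align)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
                epoch_w.append(len(sel))
            train_loss = float(np.average(epoch_losses, weights=epoch_w))
            val_loss = run_loss(arr["val"], max(tc.batch_size, 64))
            history.append({"epoch": epoch, "lr": lr,
                            "train_loss": train_loss, "val_loss": val_loss})
            if verbose:
                print(f"epoch {epoch:3d}  lr {lr:.2e}  "
                      f"train {train_loss:.4f}  val {val_loss:.4f}")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = net.state_dict()
                best_epoch = epoch
            elif tc.patience and epoch - best_epoch >= tc.patience:
                break
        net.load_state_dict(best_state)
        net.eval()
        return PestDensityResults(self, net, pre, tc,
                                  pd.DataFrame(history),
                                  {"train": idx_train, "val": idx_val,
                                   "test": idx_test}, arr, seed)


class PestDensityResults:
    """Fit results: fitted network, history, held-out predictions, metrics."""

    def __init__(self, model: PestDensityModel, network: PestDensityNetwork,
                 preprocessor: Preprocessor, train_config: TrainConfig,
                 history: pd.DataFrame, splits: dict, arrays: dict,
                 seed: int):
        self.model = model
        self.network = network
        self.preprocessor = preprocessor
        self.train_config = train_config
        self.history = history
        self.splits = splits
        self.arrays = arrays
        self.seed = seed
        self._metrics: dict[str, MetricsRecord] = {}

    # -- prediction --------------------------------------------------------
    def predict_arrays(self, arrays: dict, batch_size: int = 128
                       ) -> np.ndarray:
        self.network.eval()
        preds = []
        with no_grad():
            for lo in range(0, len(arrays["y"]), batch_size):
                batch = {k: v[lo:lo + batch_size] for k, v in arrays.items()}
                preds.append(self.network(batch).data)
        return np.concatenate(preds)

    def predict(self, dataset: MultimodalDataset | None = None) -> np.ndarray:
        """Predict densities for a dataset (default: the test split)."""
        if dataset is None:
            return self.predict_arrays(self.arrays["test"])
        return self.predict_arrays(self.preprocessor.transform(dataset))

    def metrics(self, split: str = "test") -> MetricsRecord:
        if split not in self._metrics:
            arr = self.arrays[split]
            self._metrics[split] = evaluate(arr["y"],
                                            self.predict_arrays(arr))
        return self._metrics[split]

    def predictions_frame(self, split: str = "test") -> pd.DataFrame:
        arr = self.arrays[split]
        return pd.DataFrame({"sample_id": self.splits[split],
                             "y_true": arr["y"],
                             "y_pred": self.predict_arrays(arr)})

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pest Density Estimation — fit summary",
            "=" * 54,
            f"modalities:        {', '.join(cfg.modalities)}",
            f"embedding dim d:   {cfg.d}   heads: {cfg.n_heads}   "
            f"feature channels: {cfg.feature_channels}",
            f"objective:         {cfg.loss} (eps={cfg.eps}), "
            f"lambda_align={cfg.lambda_align}",
            f"epochs run:        {len(self.history)} "
            f"(seed {self.seed})",
            "-" * 54,
        ]
        for split in ("train", "val", "test"):
            lines.append(f"{split:>5}: {self.metrics(split)}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"],
                label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], label="val")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: npz archive with a JSON header entry."""
        state = self.network.state_dict()
        header = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.model.config).items()},
            "seed": self.seed,
            "shapes": {k: list(v.shape) for k, v in state.items()},
            "norm_stats": self.preprocessor.stats.to_dict(),
            "crc": zlib.crc32(b"".join(v.tobytes()
                                       for _, v in sorted(state.items()))),
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **state)

    @staticmethod
    def load_state(path) -> tuple[dict, dict]:
        with np.load(path) as archive:
            header = json.loads(bytes(archive["__header__"]).decode())
            state = {k: archive[k] for k in archive.files
                     if k != "__header__"}
        return header, state
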