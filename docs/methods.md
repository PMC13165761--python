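# Methods

## Scope and shape

`pestfusion` estimates a continuous pest population density (individuals
per m²) per field sample from three modalities: a canopy image patch, a
window of environmental sensor readings, and a short sequence of
pheromone-trap counts. The public surface is statsmodels-style: a
`PestDensityModel` built from a `MultimodalDataset`, whose `fit()` returns
a `PestDensityResults` carrying the fitted network, training history,
held-out predictions, metrics and a `summary()` table. Underneath, the
library is organized by pipeline stage (`synthetic`, `preprocessing`,
`encoders`, `fusion`, `regression`, `metrics`, `experiments`), and a thin
`click` CLI wraps the same functions.

The network runs on a package-local reverse-mode autodiff engine over
NumPy (`pestfusion.nn`): tensors record the operations applied to them,
and a topological backward pass accumulates gradients. Every primitive's
gradient is tested against central finite differences. The engine frees
each computation graph eagerly after `backward()` (the backward closures
form reference cycles that CPython's counter alone cannot reclaim) and
keeps float32 throughout — two choices that matter for CPU memory and
speed far more than FLOPs do at this scale.

## Preprocessing

* **Images.** Sliding-window cropping (row-major, 0-based, top-left
  origin); global standardization `(X − μ)/σ` with μ, σ computed on the
  *training split only* and frozen (no leakage into validation/test).
  Augmentation is a stochastic sampler over rotations, flips and a linear
  brightness/contrast map `αX + β` (clipped); exact 90° multiples rotate
  by lossless index permutation, other angles by bilinear resampling with
  reflected edges. Augmentation probabilities and parameter ranges are
  configuration with documented defaults — no canonical values exist for
  them, so they are deliberately exposed rather than hard-coded.
* **Sensor series.** Linear interpolation onto a target grid (refusing to
  extrapolate), neighborhood-mean imputation of missing entries within a
  closed window ±δ (excluding the missing point itself; an empty
  neighborhood raises listing the offending timestamps), then
  per-variable standardization. The model pipeline uses δ = 3 sensor
  steps and widens the window geometrically in the rare case a long gap
  run leaves a point with no observed neighbor — a documented fallback
  preferred over aborting a whole training run.
* **Trap counts.** Centered moving-average smoothing with radius k; near
  the boundary the window shrinks symmetrically so every output is a true
  mean and the length is preserved. Counts convert to density by dividing
  by the trap's effective attraction area.

## Architecture and numerical choices

Defaults: shared embedding `d = 32`, 4 attention heads (8 available),
conv widths (8, 16, 32) over three stride-2 stages so a 64-px patch gives
an 8×8×32 feature map and 64 visual tokens; environment context channels
equal the feature channels (required by the affine modulation);
regression head 32 → 16 → 8 → 1 with ReLU and dropout 0.1; robust-loss
threshold ε = 1.0 (the standard smooth-L1 convention); alignment weight
λ = 0.1. None of these have canonical published values; all are
configuration.

Decisions where the design was genuinely open:

* **Two environmental paths.** The alignment path uses a lightweight
  projection + sinusoidal positions; the modulation path has its own
  conv stack producing the context vector. They serve different roles
  (token-level interaction vs a global conditioning signal) and share no
  weights.
* **Normalization inside the context encoder** is per-timestep over
  channels (layer style) rather than batch statistics: batch-size
  independent, no running state, exactly deterministic at inference.
* **Combining the two fusion outputs.** The enhanced feature map is
  tokenized by its own projection and *added* token-wise to `Z_align`;
  both pathways stay gradient-connected and shapes are preserved. Plain
  concatenation along the token axis replaces this in the
  "no-alignment" ablation.
* **Alignment-loss mean** is the per-sample mean over tokens (not a batch
  mean): that is the only reading that yields a per-example loss
  compatible with minibatch training.
* **Saliency mask network** is a single affine layer + sigmoid per token;
  a deeper variant is available behind configuration. The attention pool
  queries `[global token; S⁺]` and attends over `[S⁺; S⁻]`, so
  aggregation focuses on the density-sensitive component while the
  complement remains visible as context.
* **Objective.** The smooth-L1 robust loss is the default; a plain MSE
  objective is available behind a config switch (`loss="mse"`) because
  both conventions are common for this task and they differ materially in
  outlier handling. MAPE is reported with the relative error floored at
  `max(|y|, 1e-6)` — zero-density samples otherwise divide by zero; this
  makes MAPE large whenever near-zero densities are present, which is a
  property of the metric, not a defect of the fit.
* **Modality ablations are structural.** An absent modality's branch is
  not built at all (no zero-filling); without the image the remaining
  token sequences are concatenated and pooled directly.

Training follows a fixed protocol: Adam, cosine-annealed learning rate,
70:15:15 split by sample id with a seeded shuffle (5-fold CV available as
an alternative harness), early stopping on validation loss, best-epoch
weights restored. All randomness (splits, init, dropout, batch order)
derives from one seed via `SeedSequence`, so end-to-end runs are
bit-reproducible.

## The synthetic benchmark

The generator defines the study conditions; every default below was fixed
once, before the model was evaluated against it.

* **Strata.** Density strata in individuals per trap: low 0–20, medium
  21–50, high > 50 (capped at 80 for sampling), with prevalences
  42.5 / 35.8 / 21.7 %. A per-trap rate λ is drawn uniformly inside the
  stratum and the label is `y = λ / A` with effective attraction area
  `A = 50 m²` (so densities span 0–1.6 individuals/m²).
* **Latent law.** `y = y_max · g(d) · exp(c_T z_T + c_H z_H)` with
  `g` a normalized logistic in the damage fraction `d`
  (`y_max = 3.0, k = 6, mid = 0.45`; `g(0)=0`, `g(1)=1`, strictly
  increasing) and `z_T, z_H` the standardized per-sample temperature and
  humidity offsets (`c_T = 0.30`, `c_H = 0.18`; wind, rainfall and
  illumination have zero effect by construction — they exist to give the
  sensitivity harness known null factors). The damage fraction is solved
  from the law (stratum-first sampling, with rejection of the rare
  unreachable top-of-range combinations), so the label satisfies the law
  exactly and parameter recovery is well posed — fitting the true
  functional form to generator output recovers all five parameters within
  5 %.
* **Images.** Procedurally textured canopy plus elliptical damage blobs;
  the blob field is thresholded at the exact pixel count implied by `d`,
  so the mask doubles as a ground-truth oracle (relative error of the
  rendered damage fraction is below 1 pixel).
* **Sensor windows.** 48 steps at 30-minute cadence (24 h, so the diurnal
  cycle is fully covered): per variable a mean + per-sample offset +
  diurnal sinusoid + AR(1) noise, with physical clip ranges, sparse
  exponential bursts for rainfall, and 5 % missingness injected uniformly
  at random.
* **Trap counts.** 6 visits, each an independent Poisson draw with mean
  `y · A · η`, where `η` is a per-sample lognormal trap-efficiency factor
  (σ = 0.3, mean 1). Without η a trap is a near-sufficient statistic for
  the label and the other modalities become irrelevant; with it, the
  trap-implied density correlates strongly but imperfectly with truth,
  matching how trap records relate to synchronized manual surveys in the
  field. Setting `trap_noise_sigma = 0` recovers the pure Poisson trap.

What the generator does **not** emulate: spatial structure across
neighboring fields, weather-realistic covariance between variables,
species-specific phenology, label noise from annotation, and
distribution shift between seasons. Passing the benchmark therefore shows
that the architecture can recover a nonlinear multimodal generative law
from realistic sample sizes — not that it transfers to any particular
real survey.

## Benchmark problem sizes

The recovery benchmark uses n = 2000 samples per seed (64-px patches,
d = 32), three seeds, 16 epochs at learning rate 2e-3 (batch 64) — a
deliberately scaled-down protocol that a single CPU core completes in
minutes. The full-protocol defaults (100 epochs, lr 1e-4, batch 16,
patience 10) remain the `TrainConfig` defaults for real use.

## Known limitations

* The robust loss is once- but not twice-differentiable at |e| = ε;
  optimizers that rely on curvature would see a kink there.
* Permutation importance attributes error increase, not causal effect;
  correlated factors (temperature and humidity both enter the
  hydrothermal modifier) share importance in a way that depends on the
  model's internal reliance, so the scores are a ranking tool, not
  effect-size estimates.
* The engine is single-threaded NumPy: adequate for the benchmark scale,
  not for high-resolution imagery or large backbones.
* `MAPE` with a floored denominator is reported for completeness but is
  close to meaningless when many true densities are near zero; MAE, RMSE
  and R² are the metrics to read.
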