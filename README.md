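# pestfusion

Multimodal estimation of field-scale pest population density from
crop-canopy image patches, environmental sensor time series, and
pheromone-trap counts.

## The problem

Integrated pest management needs the *population density* `y`
(individuals per m²) at field scale, not per-image detections. No single
sensing modality measures it well: canopy imagery shows damage but not the
environmental drivers of population growth; micro-weather stations record
those drivers (temperature, humidity, wind, rainfall, illumination) but
carry no spatial signal; pheromone traps observe the pests directly but
sparsely and noisily — a trap count over a visit interval, divided by the
trap's effective attraction area `A` (m²), is only a stochastic proxy of
the local density. `pestfusion` is for quantitative ecologists and
agricultural data scientists who want a regression model that fuses all
three streams into one density estimate, together with a fully synthetic
benchmark whose generative law is known, so every claim the model makes
can be checked against ground truth.

## The model

Each modality is encoded into tokens in a shared d-dimensional space: a
small strided convolutional backbone for the image patch (feature map
`F_v`, flattened positions as visual tokens `F_uav ∈ R^{N×d}`), a
per-timestep projection with sinusoidal positions for the sensor window
(`F_env ∈ R^{T×d}`), and a per-visit affine lift for smoothed trap counts
(`F_trap ∈ R^{M×d}`). Fusion happens in two coupled mechanisms:

* **Cross-modal alignment.** Multi-head scaled dot-product attention with
  the visual tokens as queries and `[F_env; F_trap]` as keys/values,
  followed by a residual connection and layer normalization:
  `Z_align = LayerNorm(F_uav + MHA(F_uav, [F_env; F_trap]))`. An explicit
  first-order alignment loss
  `L_align = ‖μ(F_uav) − μ(F_env)‖² + ‖μ(F_uav) − μ(F_trap)‖²`
  (per-sample token means) pulls the modality centroids together.
* **Environment-aware enhancement.** The raw sensor window is summarized
  into a context vector `z` by a projection and two temporal conv blocks;
  `z` generates a sigmoid channel gate `a ∈ (0,1)^C` and bias `b`, applied
  as a conditional affine modulation `F̃_v = F_v ⊙ (1 + a) + b`, followed
  by a 1×1-conv sigmoid spatial weight map. Because `a` is bounded,
  `‖F̃_v‖_F ≤ (1 + ‖a‖_∞)‖F_v‖_F + √(HW)·‖b‖₂` — enforced as a test.

The fused token sequence is softly split by a per-token saliency mask
(`S⁺ = M ⊙ S`, `S⁻ = (1−M) ⊙ S`), pooled by attention around a learned
global token, and mapped to the scalar density by a three-layer
progressively compressed MLP trained with a smooth-L1 (Huber-style)
objective: quadratic for |error| < ε, linear beyond. Training uses Adam
with cosine-annealed learning rate, early stopping on a validation split,
and the composite objective `L = L_d + λ·L_align`.

Everything — including the autodiff engine the network runs on — is
NumPy; there is no deep-learning framework dependency.

## Worked example

```python
import pestfusion as pf

scene = pf.SceneConfig(n_samples=2000, patch_size=64, seed=0)
data = pf.MultimodalDataset.from_samples(pf.generate_dataset(scene))
model = pf.PestDensityModel(data)          # full three-modality model
result = model.fit(pf.TrainConfig(epochs=16, batch_size=64,
                                  learning_rate=2e-3, lr_min=1e-4,
                                  patience=0), seed=0)
print(result.summary())
```

prints (seed 0):

```
Pest Density Estimation — fit summary
======================================================
modalities:        image, env, trap
embedding dim d:   32   heads: 4   feature channels: 32
objective:         robust (eps=1.0), lambda_align=0.1
epochs run:        16 (seed 0)
------------------------------------------------------
train: MAE=0.0800  RMSE=0.1076  MAPE=99.0%  R2=0.9413  (n=1400)
  val: MAE=0.0822  RMSE=0.1091  MAPE=47.4%  R2=0.9326  (n=300)
 test: MAE=0.0886  RMSE=0.1151  MAPE=100.9%  R2=0.9395  (n=300)
```

Held-out MAE of 0.089 individuals/m² on densities spanning 0–1.6
individuals/m² (an R² of 0.94): the fused model recovers the latent
density law of the generator. The large MAPE is an artifact of near-zero
true densities in the low stratum (relative error is floored, not
dropped). An image-only variant of the same architecture reaches MAE
0.149 / R² 0.79 on the same split — the environmental and trap modalities
carry real signal beyond canopy damage. `pestfusion.experiments` exposes
the ablation, modality-combination and permutation-importance harnesses
that quantify this systematically, e.g.:

```python
from pestfusion.experiments import sensitivity_analysis
sensitivity_analysis(result).frame()
#          factor  delta_mae  delta_rmse  importance
#     temperature   0.095747    0.145616    0.672733
#        humidity   0.044775    0.066138    0.314597
#      wind_speed  -0.000124    0.000871    0.000000
#        rainfall  -0.000589    0.000759    0.000000
#    illumination   0.001803    0.001719    0.012669
```

matching the generator's design: temperature and humidity drive the
hydrothermal modifier; wind and rainfall have no effect on density.

A command-line interface wraps the same functionality
(`pestfusion generate|preprocess|train|evaluate|ablate|modality|sensitivity|benchmark`),
each subcommand taking a YAML config plus `--seed` and `--out-dir`.

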