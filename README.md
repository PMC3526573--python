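# colonyscan

Label-free quantification of stem-cell colonies co-cultured on feeder
cells, from phase-contrast microscopy images — plus the perfusion-physics
arithmetic for the parallel-plate culture chamber such cultures grow in.

## The problem

Adherent stem-cell cultures are hard to monitor: there is no optical
density to read, and colonies of human embryonic stem cells (hESC) sit on
a feeder layer of fibroblasts that has almost the same brightness in phase
contrast. Intensity thresholding cannot separate the two populations —
but their *textures* differ sharply: colonies are carpets of small,
tightly packed cells (fine isotropic granularity, bright halo at the rim),
while the feeder layer is sparse, elongated cells. `colonyscan` turns that
texture difference into colony counts, areas, and confluency, image by
image, so culture progress can be tracked quantitatively without dyes.

## The method

For each pixel, the local texture is summarised with **Basic Image
Features (BIFs)**. From the scale-normalised responses of
derivative-of-Gaussian filters up to second order
(c₀₀, c₁₀, c₀₁, c₂₀, c₁₁, c₀₂ at scale σ, with cᵢⱼ = σ^(i+j) ∂^(i+j)G_σ ∗ I),
each pixel is assigned the class with the largest score among

| class | score |
|---|---|
| flat | ε·c₀₀ |
| slope | 2·√(c₁₀² + c₀₁²) |
| dark blob / light blob | ±λ, λ = c₂₀ + c₀₂ |
| dark line / light line | (γ ± λ)/√2, γ = √((c₂₀ − c₀₂)² + 4c₁₁²) |
| saddle | γ |

BIFs are computed at four scales σ = 0.7, 1.4, 2.8, 5.6 px with ε = 0.11,
and a 25×25 uniformly weighted window around each pixel collects a 7-bin
label histogram per scale — a 28-element feature vector whose per-scale
bins sum to 625. A **random forest** (20 trees, 5 candidate variables per
split) maps the feature vector to colony/background. The raw binary map is
cleaned by discarding objects smaller than 4000 px and filling enclosed
holes smaller than 6000 px; surviving components are the colonies. Pixel
counts convert to physical areas with 2.86 µm²/pixel (4× objective,
1280×960), and confluency is the fraction of colony pixels. Agreement with
a reference annotation is scored as F = 2TP/(2TP + FP + FN), and
confluency error as bias, RMSE and precision = √(RMSE² − bias²).

Because no microscope images ship with the package, a **synthetic
generator** renders the two-texture structure procedurally (granular
colony interiors, stroke-like fibroblast background, uneven illumination,
rim halo, noise) with exact ground-truth masks, making the full pipeline
trainable and testable end to end.

The `perfusion` module covers the companion flow physics of the 13 × 4 mm,
450 µm-high perfusion chamber: wall shear between infinite parallel plates
τ_w = 6μQ/(h²w), its linear decay τ(z) = τ_w(1 − 2z/h) above the culture
plane, residence time V/Q, media-exchange rate and seeding density.

## Worked example

```python
from colonyscan import (GeneratorConfig, PipelineConfig, generate,
                        make_training_set, train, segment)

# train a pixel classifier on three synthetic fields
train_cfgs = [GeneratorConfig(seed=s) for s in range(100, 103)]
model = train(make_training_set(train_cfgs, pixels_per_image=10_000, seed=0), seed=0)

# segment a new field and quantify it
img, truth, _ = generate(GeneratorConfig(seed=42))
labels, m = segment(img, model, PipelineConfig())
print(f"colonies detected : {m.n_colonies}")
print(f"total colony area : {m.total_area_mm2:.4f} mm^2")
print(f"confluency        : {m.confluency:.3f}  (ground truth {truth.mean():.3f})")
```

prints

```
colonies detected : 1
total colony area : 0.0723 mm^2
confluency        : 0.101  (ground truth 0.099)
```

— one colony found, occupying 10.1% of the field against a true 9.9%; the
pixel F-score of this mask against the ground truth is 0.974.

The same chain is scriptable from the shell (`colonyscan train / segment /
quantify / evaluate / simulate / perfusion`). For instance:

```bash
$ colonyscan perfusion
{
  "flow_ul_h": 300.0,
  "wall_shear_Pa": 0.000132,
  "shear_at_15um_Pa": 0.000123,
  "residence_min": 4.68,
  "exchange_ml_day_cm2": 13.85,
  "area_cm2": 0.52
}
```

i.e. at 300 µl/h the cells see ≈1.3×10⁻⁴ Pa of wall shear — two orders of
magnitude below reported detachment thresholds for hESC — the chamber
medium turns over every ≈4.7 minutes, and each cm² of culture receives
13.8 ml of fresh medium per day.

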