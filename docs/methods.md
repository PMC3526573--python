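# Methods

## Pixel texture: multiscale Basic Image Features

Each pixel's local structure is summarised by a seven-way classification
(flat, slope, dark/light blob, dark/light line, saddle) of the
scale-normalised Gaussian-derivative 2-jet. Scale normalisation
(cᵢⱼ = σ^(i+j)·∂^(i+j)G_σ ∗ I) makes the seven class scores commensurable
and the labelling invariant to multiplying the image by a positive
constant, since every score is homogeneous of degree 1 in the intensities.
The flatness parameter ε (default 0.11) sets how readily weak structure is
dismissed as flat: the flat score is ε·c₀₀ against derivative-driven
scores for the other six classes, so brighter regions need proportionally
stronger local structure to escape the flat label.

Numerical choices:

- **Kernels.** Derivative-of-Gaussian kernels are sampled analytically and
  truncated at 4σ. Second-derivative kernels are DC-corrected (the kernel
  mean is subtracted) so a constant image yields exactly zero derivative
  response; sampled-and-truncated kernels otherwise retain a relative DC
  leak of order 10⁻⁵, enough to produce spurious non-flat scores on bright
  uniform regions. First-derivative kernels are odd-symmetric and need no
  correction. Filtering is separable (two 1-D passes); an independent
  dense 2-D convolution oracle in the test suite confirms agreement to
  better than 1e-8 relative.
- **Boundaries.** Reflective (edge-repeating) padding for both filtering
  and histogram windows, avoiding artificial gradient rings at the image
  border.
- **Ties.** Argmax ties break to the lowest class index (flat first);
  with continuous-valued images ties are a measure-zero event, and the
  rule only exists to make labelling deterministic.
- **Scales and window.** Defaults: σ ∈ {0.7, 1.4, 2.8, 5.6} px, ε = 0.11,
  25×25 uniformly weighted histogram window. Per scale, the seven bins of
  an interior pixel sum to 625; concatenating four scales gives the
  28-element descriptor. Histograms are raw counts, not frequencies.

## Pixel classification

A random forest (20 trees, 5 candidate variables per split, majority vote
at threshold 0.5) maps descriptors to colony/background. The forest is
scikit-learn's `RandomForestClassifier` held behind the package's
`ColonyClassifier` surface; tree depth is not limited and the voting
threshold is 0.5, both declared defaults rather than tuned values. Every
fitted model stores a fingerprint of the feature configuration (scales, ε,
window) and refuses to predict on features computed under a different
configuration — the 28-feature contract is enforced, not assumed.
Training is reproducible given the seed; persistence is a versioned
joblib archive embedding the fingerprint.

## Cleanup and metrics

The raw binary map is cleaned in the order: remove 8-connected objects
with fewer than 4000 pixels, then fill 4-connected enclosed background
components (not touching the border) with fewer than 6000 pixels, with
hole sizes measured after object removal. Both thresholds are strict
(`<`), so a 4000-pixel object survives and a 3999-pixel object does not.
The 8-object/4-hole connectivity pair is the standard complementary
choice that prevents a background component from threading through an
8-connected object boundary. Cleanup is idempotent and only ever removes
whole small objects or adds whole small holes; both properties are tested
against a brute-force flood-fill oracle.

Metrics: total area = positive pixels × calibration (2.86 µm²/pixel for a
4× objective at 1280×960; other setups must supply a calibration
explicitly), confluency = positive pixels / all pixels, mean area =
total / colony count (reported as 0 and flagged when no colonies remain).
Merged colonies are counted as one; no watershed splitting or temporal
tracking is attempted.

## Evaluation statistics

Per image-pair: F = 2TP/(2TP + FP + FN) and confluency error
Δ = estimated − reference. Over a test set: bias = mean Δ with a
Student-t 95% confidence interval (small-sample appropriate; omitted with
a warning below two pairs), RMSE = √(mean Δ²), and precision defined as
√(RMSE² − bias²) — the standard deviation of the errors around their
mean, so precision² + bias² = RMSE² holds exactly by construction.

## Synthetic image generator

The generator emulates the features of feeder/colony phase-contrast
fields that drive the segmentation problem, on a 0–1 luminance scale with
background level 0.5:

- **Colony geometry.** 1–6 colonies per 500×500 field, base radii 40–150
  px, outlines perturbed radially by a smooth random harmonic function
  (harmonics 2–6, relative amplitude 0.12) so border pixels are genuinely
  ambiguous rather than lying on perfect circles.
- **Colony texture.** Dense isotropic granularity: Gaussian bumps of
  radius 2–5 px stamped at 0.07 per colony pixel, amplitude ±0.12×U(0.5,1).
- **Background texture.** Sparse anisotropic strokes (fibroblast bodies):
  rotated rectangles 30–80 px long and 3–6 px wide at 2.4×10⁻⁴ per image
  pixel, amplitude ±0.10×U(0.5,1), lightly smoothed.
- **Field nuisances.** A linear illumination gradient of amplitude 0.08
  in a random direction, a bright halo at colony rims (strength 0.15,
  smoothed), and additive Gaussian noise of SD 0.02.

The contrast and density constants were fixed once on signal-to-noise
grounds before any end-to-end evaluation: for a background level of 0.5
the flat score is ε·c₀₀ ≈ 0.055, which must dominate the noise-driven
slope score (≈0.016 at σ = 0.7 for noise SD 0.02) so plain background
stays flat, while texture amplitudes of ≈0.1 produce derivative responses
well above 0.055 at their matching scales so textured pixels do not.

What the generator does **not** emulate: physically modelled
phase-contrast optics (halo and shade-off are phenomenological), cell
debris, dense fibroblast clusters, focus drift, vignetting beyond a
linear ramp, or annotation noise. Synthetic benchmark scores are
therefore an upper bound on real-image performance: the package's
held-out synthetic F-scores (≈0.97 mean) exceed what the same algorithm
achieves on real microscope images (≈0.90 reported for this class of
data), and passing the synthetic benchmark shows the pipeline is
implemented correctly, not that any particular real culture will
segment at that accuracy.

Training sets are balanced 1:1 by class with 2×10⁵ pixels by default
(desk-scale stand-in for expert-annotated training data of order 10⁷
pixels); requesting more pixels of a class than an image contains is an
error, so benchmark drivers select fields containing at least the
per-class quota — the counterpart of an annotator training on
informative fields.

## Perfusion physics

All quantities are SI internally; µl/h, mm and µm are converted at the
interface. Wall shear uses the infinite-parallel-plate solution
τ_w = 6μQ/(h²w) with the full 450 µm gap, μ = 6.96×10⁻⁴ Pa·s and
ρ = 993.2 kg·m⁻³ (water at 37 °C). The shear profile τ(z) = τ_w(1 − 2z/h)
is the exact derivative of the plane-Poiseuille parabola and is returned
as a magnitude. The analytical model ignores the recessed culture plane
and the flow-equalisation barriers, so it slightly overestimates the
near-plane shear; finite-element treatments of the same geometry put the
15 µm value about 10% lower, and the module documents the analytical
number as an upper-bound approximation. No finite-element solving is
attempted. Residence time is V/Q for the rectangular chamber volume;
media-exchange rate is Q per day per culture area.

## Problem sizes

The test suite trains and evaluates on 256×256 synthetic fields with
25–60 px colonies; the acceptance benchmark uses the full 500×500 default
geometry with 10 training and 20 evaluation fields and 2×10⁵ training
pixels. These sizes give stable statistics (F-score SD under 1% across
seeds) while keeping a full run in the tens of seconds on one CPU.
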