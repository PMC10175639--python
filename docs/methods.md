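# Methods

This note documents the models, conventions and numerical choices behind
`sonolbp`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort model

The generator emulates the *structure* of a two-group musculoskeletal
ultrasound study — not the physics of any device. Each subject carries the
14-ROI acquisition layout (MF at two levels × two sides × two positions;
ES/TLF/TrA at L2-L3 × two sides, prone), an SWE (mean, std) pair per ROI,
two side-averaged thicknesses, demographics and a VAS score.

**B-mode speckle.** An ROI image is built as
`exp(noise_scale · G) · Gamma(k, 1/k)`, log-compressed with
`log1p(40·env) / log1p(40·12)` and quantized to 8 bits, where `G` is white
Gaussian noise smoothed with an anisotropic Gaussian kernel (axial σ 1.5 px,
lateral σ 3.0 px, then normalized to unit variance) and the gamma factor is
unit-mean multiplicative speckle with shape k = 4. This is standard
envelope-statistics phenomenology: a smooth echogenicity background times
fully-developed-speckle-like noise, then display compression. The
moderate–severe class multiplies both correlation lengths by
`1 + texture_effect` and divides the gamma shape by the same factor
(longer-range, heavier-tailed texture). With `texture_effect = 0` the two
classes draw identical images from identical generator states.

**SWE elasticity.** Per-ROI mean stiffness is log-normal with expectation
20 kPa (mild) and 20 + `swe_effect` kPa (moderate–severe), log-σ 0.2 — values
in the range reported for lumbar muscle, chosen once as plausible defaults,
not calibrated to any dataset. The per-ROI SWE std is log-normal around 15%
of the mean.

**Thickness.** Log-normal around 1.8 mm (TLF) and 3.5 mm (TrA), log-σ 0.15,
shifted by `thickness_effect` mm in the moderate–severe class. The default
shift is 0: thickness is carried as a feature but is uninformative unless
the user plants an effect.

**Demographics and VAS.** Sex, weight, height and age are sampled near the
published group moments (truncated at physiologic bounds); VAS is uniform on
[1, 3] (mild) and (3, 8] (moderate–severe). Demographics are metadata only —
they are never features, so the exchangeability guarantee concerns the
measured channels (images, SWE, thickness).

**Defaults as study conditions.** `CohortConfig()` fixes 24 mild + 28
moderate–severe subjects, 64×64-pixel ROIs, `texture_effect = 0.3`,
`swe_effect = 6.0` kPa, `thickness_effect = 0`. These defaults make the two
classes clearly separable; the informative experiments vary the effects
downward (the test suite uses none/half/full levels and an
elasticity-only configuration).

**What the generator does not emulate:** acoustic wave propagation, RF
signals, depth-dependent attenuation or focusing, operator variability in
ROI placement, anatomical structure (fascicles, fascia boundaries), or any
correlation between demographics and imaging. Passing tests therefore show
that the *pipeline machinery* is correct and calibrated — not that the
classification result transfers to patients.

## Feature bank conventions

Choices the literature leaves open are fixed as follows (all exercised by
tests; `levels` is a CLI knob):

* **Quantization**: uniform binning of [0, 255] into Q = 32 equal-width bins
  (`floor(v·Q/256)`, clipped) before GLCM/GLRLM.
* **GLCM**: distance 1, four directions with offsets 0°→(0, 1), 45°→(−1, 1),
  90°→(−1, 0), 135°→(−1, −1); single-direction counts, *not* symmetrized —
  otherwise the Symmetry statistic `1 − ½·Σ|P − Pᵀ|` would be identically 1.
  Homogeneity uses the inverse-difference kernel `1/(1+|i−j|)`; entropy uses
  the natural logarithm with 0·ln 0 = 0; correlation is 0 by convention when
  a marginal variance vanishes (constant quantized image).
* **GLRLM**: maximal constant-gray runs along each line of the direction
  (rows, columns, anti-diagonals, diagonals); Galloway statistics on raw
  counts with N_r = total runs: SRE = Σp/j²/N_r, LRE = Σp·j²/N_r,
  GLNU = Σᵢ(Σⱼp)²/N_r, RLNU = Σⱼ(Σᵢp)²/N_r, RP = N_r/N_pixels.
* **First-order statistics**: population (ddof 0) moments; skewness m₃/σ³
  and *non-excess* kurtosis m₄/σ⁴ (normal → 3), both 0 by convention when
  σ = 0; histogram energy over the 256-bin normalized histogram; IOD is the
  raw pixel sum.
* **LBP**: integer 8-neighbor radius-1 codes (no interpolation of diagonal
  neighbors, unlike interpolated-ring variants), comparison `neighbor ≥
  center`, bit 0 east, counter-clockwise; energy/entropy of the 256-bin
  normalized code histogram.
* **MFAF**: columns are the axial direction (ultrasound texture periodicity
  is axial). Each column is mean-removed. *Maximum entropy*: Burg AR(8)
  coefficients (implemented vectorized across columns; validated against an
  independent implementation), power spectrum 1/|A(e^{i2πf})|² on a
  256-point grid over [0, 0.5] cycles/pixel **refined around the AR pole
  frequencies** — a fixed grid cannot resolve a resonance whose pole radius
  is within 10⁻⁶ of the unit circle, and without refinement the spectral
  centroid of a pure tone is biased by several hundredths. The centroid is
  trapezoid-integrated on the refined grid. *Multi-window*: mean of K = 4
  sine-tapered periodograms (512-point FFT). A zero-power column takes the
  flat-spectrum centroid 0.25 under both estimators.
* **SWE features** are acquisition-provided scalars passed through, never
  computed from the B-mode patch.
* **Naming**: every feature carries a structured identity
  (level, side, muscle, position, family, statistic, qualifier) serialized
  as e.g. `L2-L3_R_TLF_GallowayFeature.RLNU (prone position, direction = 0°)`;
  the two thickness features use side tag `LR` (side-averaged) and are
  attributed to L2-L3/prone, which reproduces the denominators 456/114/115/115
  by muscle, 572/228 by level and position, 399/399(+2) by side.

## Selection and classification

* Standardization uses population moments; σ = 0 columns map to 0.
* The two-group ANOVA F equals the squared pooled-variance t statistic and is
  invariant to affine feature rescaling (both tested). A feature with zero
  within-group variance but distinct means scores +∞ and ranks first.
* Retained count k = floor(n · percentile/100) — exact at the operating
  point (800 × 6% = 48). Ties break by canonical feature order.
* Default protocol fits μ, σ and F inside each outer training fold
  (leakage-safe); `fit_on_all=True` reproduces the optimistic variant that
  fits them once on the whole matrix. Reports record the mode used.
* Outer CV: stratified 5-fold, shuffled with a fixed seed. Inner grid
  search: stratified 5-fold on the training fold, accuracy criterion,
  C ∈ {0.01, 0.1, 1, 10, 100}, ties to the smaller C. Decision threshold 0.
* AUC is computed from the decision scores pooled across outer folds (small
  held-out folds make per-fold AUC unstable); per-fold panels are also
  reported and their confusion counts recombine exactly to the pooled
  counts.
* Group-difference reporting for top features uses a Shapiro–Wilk gate at
  α = 0.05 per group (t-test when both pass, Mann–Whitney otherwise, exact
  for small samples), with `*`/`**` flags at p < 0.05/0.01 and p = 1 for
  constant features.

## Problem sizes in the test suite

Structural and oracle tests run on exhaustive 3×3 binary images and small
fixtures. Stochastic calibration and recovery tests run the full pipeline at
the study conditions — 52 subjects, 64×64 ROIs — over 20 seeds per check,
with feature tables cached per (condition, seed) across tests. Unit-level
pipeline tests use a 16-subject, 32×32-ROI cohort, the smallest size at
which nested stratified 5-fold cross-validation remains feasible.

## Known limitations

* The published patient-level metric panel cannot be reproduced without the
  clinical data; the synthetic defaults are not calibrated to it, and a
  perfect panel under the default effects only reflects the chosen effect
  sizes.
* Texture effects act globally on every ROI of a subject; there is no
  per-muscle effect heterogeneity knob.
* The SIFS/MIFS comparison inherits the small-cohort variance of 5-fold CV;
  conclusions in the tests are asserted on 20-seed means, not per seed.
* `burg_order` and `n_tapers` are declared constants in this version (the
  config surface validates rather than varies them).
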