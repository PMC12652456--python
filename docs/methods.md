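# Methods

`tanninspec` implements a dual-sensor hyperspectral workflow for predicting
sorghum tannin content: synthetic cohort generation, spectra I/O and ROI
extraction, CARS wavelength selection, data- and feature-level fusion,
PLS/SVR/CNN regression, and calibration diagnostics. This note records the
models, conventions and design choices behind each stage.

## Synthetic cohort generator (`simgrain`)

The generator emulates a 240-sample sorghum cohort measured on two pushbroom
sensors — a VNIR lens (646 bands, 430–900 nm) and a SWIR lens (148 bands,
950–1650 nm) — with wet-chemistry tannin reference values.

**Reference values.** True tannin contents are drawn from a truncated normal
on [0.05, 2.56] % whose parent (μ₀, σ₀) is solved numerically so the
*truncated* moments match the target mean 1.18 % and SD 0.732 %. The target
SD slightly exceeds the uniform limit (2.51/√12 ≈ 0.7246), so no truncated
normal attains it exactly; the least-squares solution sits near that limit
and delivers SD ≈ 0.718. By default the draw is a seeded Latin hypercube
over the CDF (`stratified=True`): the marginal law is unchanged, but a
single cohort's sample moments concentrate tightly on the targets, which is
the generator's job — emulating a cohort with reported summary statistics.
Plain i.i.d. sampling is available via `stratified=False`. Recorded
reference values add assay noise (SD 0.10 %, consistent with the 5–15 %
relative SD typical of spectrophotometric tannin assays) and are clipped to
the reporting range; the latent true values drive the spectra.

**Spectra.** Each sample's reflectance is

    R(λ) = baseline(λ)·(1 + m_i) + o_i − Σ_k d_k·G(λ; c_k, w_k) + ε(λ),

clipped to [0, 1], with per-sample multiplicative scatter m_i ~ N(0, 0.03²),
additive offset o_i ~ N(0, 0.01²), white noise SD 0.006, and Gaussian
absorption features G at the landmark centers a spectroscopist expects for
pigmented, tannin-rich grain: 530/580/650/670 nm chromophore bands, 845/890
nm C–H/C–O overtones, and 1130 (C–H), 1402/1480 (O–H), 1558 (N–H) nm
combination bands. Baselines are fixed low-order shapes per sensor (VNIR
rising through the red edge; SWIR gently declining with a reflection peak
near 1130 nm and a broad depression toward 1480 nm); their coefficients are
simulator configuration, not scientific claims.

**Planted signal structure.** Three deliberate choices shape what models can
and cannot extract:

1. *Shared curvature.* Every tannin band follows one depth shape
   g(T) = T + 2.5·T². If bands had different quadratic/linear ratios, a
   linear combination of two bands would reconstruct T exactly and linear
   models would be unbeatable; a shared shape makes the curvature genuinely
   inaccessible to linear calibration (best linear R² on g(T) ≈ 0.95 of the
   attainable ceiling over this tannin range).
2. *Sensor-specific latents.* VNIR tannin depths respond to a pigment
   latent correlated with tannin at ρ = 0.90 (visible bands see
   chromophores, an imperfect proxy); SWIR tannin depths respond to a
   biochemical latent at ρ = 0.78 (weak but direct overtone signature).
   Each sensor alone therefore caps at an intermediate R², and fusing the
   two independent views genuinely adds information — reproducing the
   qualitative structure VNIR ≈ 0.75 / SWIR ≈ 0.55 / fused ≈ 0.8 seen in
   real dual-sensor tannin studies.
3. *Moisture nuisance.* Moisture (mean 12 %, SD 1.5 %) correlates with
   tannin at r = 0.3 and drives the 1402/1480 nm O–H bands; the 1480 nm
   band carries a tannin×moisture cross term (0.002 per %T·%M), a second
   nonlinear pathway.

The generator does **not** emulate radiative transfer (no Kubelka–Munk),
instrument line-shape or stray-light effects, wavelength-registration
drift, detector nonlinearity, or inter-grain packing texture. Passing tests
therefore demonstrate that the pipeline's statistics behave as designed
under a controlled signal model — not that the models would reach any
particular accuracy on real grain.

Hypercubes for ROI-extraction tests replicate one sample's spectrum over
n_pixels with independent pixel noise (SD 0.01), so the ROI mean converges
to the sample spectrum at the CLT rate.

## Spectra I/O (`spectra_io`)

Spectra tables are CSV: a `sample_id` column, then one column per band
headed by the wavelength printed to three decimals (fixed dialect, bit-exact
round trips). ENVI cubes support BSQ/BIL/BIP interleaves and data types 4/5
(float32/64) and 12 (uint16 with a reflectance scale factor); other types
are rejected loudly. Wavelength-range trimming is boundary-inclusive so the
printed endpoints 430/900/950/1650 nm stay in range, and retained original
indices ride along for provenance. ROI extraction is the plain per-band
arithmetic mean over masked pixels.

## Reference assay (`chemistry`)

The tannic-acid standard curve is an OLS line of absorbance (525 nm) on
concentration, inverted for prediction. Tannin content is
T (%) = (2c/m)·100·100/(100−H) with c in mg/mL from the curve, m the sample
mass (mg) and H the moisture (%): 2c/m is the dry-mass fraction (the factor
2 folds in the 20 mL extraction volume per gram of sample), ×100 converts
to percent, and 100/(100−H) corrects to dry basis. Replicate absorbances
are averaged before inversion; with a linear curve the ordering is
immaterial. T is linear in c, inverse in m, strictly increasing in H.

## Partitioning (`datasplit`)

The hold-out split is a seeded uniform random 75/25 partition
(|calibration| = round(0.75·n); 240 → 180/60). A Kennard–Stone variant is
provided as a clearly-separate extension for users wanting distance-based
coverage. Cross-validation folds stratify the continuous target by quantile
bins (quintiles by default, automatically reduced when n/k is small) and
deal shuffled samples round-robin across folds within strata, giving fold
sizes within one of each other and fold means concentrated around the
global mean.

## CARS wavelength selection (`cars`)

Each execution runs N = 100 Monte-Carlo iterations. At iteration i a row
subsample (ratio 0.8) is drawn, a PLS model is fitted on the currently
retained bands, and absolute regression coefficients become sampling
weights. The exponential decreasing function r_i = a·e^(−k·i), with
a = (p/2)^(1/(N−1)) and k = ln(p/2)/(N−1), forces the retention count down
from r₁ = 1 (all p bands) to r_N = 2/p (two bands); the top-weight bands
survive the forced cut, and adaptive reweighted sampling (weighted draw
with replacement, deduplicated) competes the survivors. Each iteration's
retained set is scored by RMSECV — pooled root-mean-square error of
fold-held-out PLS predictions — on the full calibration block, and the
minimum-RMSECV subset wins the execution (ties: smaller subset, then
earlier iteration). An outer stability loop repeats the execution E = 10
times with independent seeds and keeps bands selected in ≥ 50 % of
executions; an empty vote falls back to the single best execution's subset
(flagged). The PLS component count inside CARS is chosen once per execution
by cross-validation up to 10 components. Both N and E are exposed; the
"repeat 100 times and keep high-frequency bands" description in the
chemometrics literature is ambiguous between them, so both interpretations
are supported.

## Fusion (`fusion`)

Data-layer fusion splices full spectra along the wavelength axis (VNIR
block first, 646 + 148 = 794 columns); feature-layer fusion concatenates
the per-sensor CARS subsets. No rescaling is applied before concatenation —
modeling consumes raw reflectance — though per-block standardization is
available off by default. Every fused column carries provenance (sensor,
original band index, wavelength), making fusion losslessly invertible.

## Regression families (`models`, `cnn`)

*PLS* (mean-centered, unscaled) selects its component count by minimizing
RMSECV over the shared stratified folds. *SVR* uses an RBF kernel on
standardized features with ε = 0.1 and an exhaustive search over the 5×6
grid C ∈ {0.1, 1, 10, 100, 1000} × γ ∈ {0.0001, 0.001, 0.01, 0.1, 1, 10},
maximizing mean held-out fold R²; exhaustive search over a 30-point grid is
at least as good as any sequential optimizer on that grid. Ties break
toward smaller C then smaller γ, deterministically.

The *CNN* is a compact 1-D convolutional network written in numpy: by
default two Conv–ReLU–MaxPool blocks (16 and 32 filters, kernel 5, pool 2),
a ReLU dense layer of width 64 with dropout 0.5, and a linear head; Adam
with initial learning rate 1e-4, step decay ×0.1 every 600 epochs, L2
1e-5, and early stopping (patience 20, min-delta 1e-3) on an internal
validation fraction with best-weight restore. Features and target are
standardized inside the wrapper. Kernels cap to the input width so narrow
CARS subsets still train, and an optional `n_restarts` refits from
independent initializations keeping the best validation loss — the
package's lightweight counterpart to a larger architecture search. All fits
are bit-reproducible under a fixed seed in single-threaded execution.

On the default synthetic cohort the two nonlinear families behave as the
planted signal predicts: the kernel SVR beats linear PLS in the majority of
seeds, and the CNN tracks the best family closely without reliably beating
the SVR. At 180 calibration samples a convolutional network has no
structural advantage over a well-tuned kernel machine on this signal — the
test suite asserts exactly that relationship (SVR ≥ PLS in majority; CNN
within 0.10 R² of the best family) rather than a strict CNN > SVR ordering,
which would not be statistically supportable at this sample size. This is a
known limitation, not a target of the package.

## Metrics (`metrics`)

R² = 1 − Σ(Ŷᵢ−Yᵢ)²/Σ(Yᵢ−Ȳ)² with Ȳ the evaluated set's own mean;
RMSE = √(Σ(Ŷᵢ−Yᵢ)²/n); RPD = 1/√(1−R²). The square-root form of RPD is the
one consistent with standard usage (RPD = SD/SEP) and reproduces the
printed diagnostic pairs 0.80→2.24, 0.79→2.18, 0.60→1.58, 0.74→1.96; the
non-root reading does not. Bias is mean(predicted − reference) — negative
bias means underestimation — and SEP is the SD of bias-corrected residuals
with an n−1 denominator. Two 95 % t-intervals are reported and labeled:
mean-level (± t·SEP/√n) and single-new-prediction (± t·SEP), because
published "single prediction" intervals are often numerically mean-level
ones. Interpretation bands are closed on the left: R² < 0.6 poor, [0.6,
0.8) good, ≥ 0.8 excellent; RPD < 1.5 insufficient, [1.5, 2.0) acceptable,
≥ 2.0 outstanding. Family comparison uses classical one-way ANOVA plus
Tukey HSD on replicate RMSEP values; residual diagnostics report mean, SD,
skewness, excess kurtosis and a Shapiro–Wilk p-value, with constant
residuals flagged degenerate rather than propagating undefined moments.

## Pipeline (`pipeline`)

`run_experiment` goes: generate/load cohort → 75/25 hold-out → CARS per
sensor **on calibration rows only** → six variants (VNIR/SWIR/Whole raw;
VNIR/SWIR/Fused features) → tune and fit the three families per variant on
calibration only → evaluate on the untouched prediction set. Tuning
functions never receive prediction indices, and a test poisons the held-out
reference values to verify every fitted model is bit-identical. RMSEP
replicates for the ANOVA come from repeated seeded hold-out splits (default
10) refitting the families on the fused-feature variant — this package's
replication protocol, chosen to match the comparison's (2, 27) degrees of
freedom. All stage seeds derive deterministically from one experiment seed,
and two runs with the same seed produce byte-identical reports.

## Problem sizes and runtimes

The analysis scripts run the full study scale (240 samples, 646+148 bands,
CARS N = 100 × E = 10, 18 models, 10 ANOVA replicates) in a few minutes on
one CPU; the CNN there uses a faster optimizer setting (learning rate 1e-3,
patience 50, two restarts) than the production defaults so the whole grid
stays desk-scale. The test suite scales stochastic suites down — CARS
N = 50 × E = 3 for the five-seed majorities, a 60-sample cohort on reduced
grids for pipeline plumbing — sizes chosen so each property is still
informative while the suite completes quickly.

## Known limitations

- The generator is phenomenological; parameter defaults are calibrated to
  summary statistics and qualitative structure, not to physical constants.
- The truncated-normal family cannot reach the target SD exactly (uniform
  limit); achieved SD ≈ 0.718 vs 0.732 target.
- The numpy CNN matches but does not beat the SVR at this sample size (see
  above); GPU-scale architecture search is out of scope.
- ENVI support covers the common float and scaled-uint16 cubes only; ROI
  masks are accepted as given, not derived from images.
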