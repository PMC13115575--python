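# Methods

`vitrispec` implements a chemometric workflow for estimating the postmortem
interval (PMI, in hours) from ATR-FTIR absorbance spectra of vitreous humor
in the 1800–700 cm⁻¹ fingerprint region.  This note documents the models,
the numerical choices, and what the synthetic test bed does and does not
establish.

## Spectral model and preprocessing

A measured spectrum is treated as a chemical signal distorted by
non-chemical acquisition effects: multiplicative scaling (effective optical
path/contact at the ATR crystal) and a low-order additive baseline
(scattering).  Preprocessing is a fixed three-step pipeline applied in this
order:

1. **EMSC** (extended multiplicative signal correction).  Each spectrum `s`
   is decomposed by ordinary least squares as

   `s ≈ a·1 + c·ν̃ + b·r`

   where `r` is the reference spectrum (the arithmetic mean of the fitting
   set), `ν̃` the wavenumber axis affinely scaled to [−1, 1], and the
   corrected spectrum is `(s − a·1 − c·ν̃)/b`.  The least-squares residual —
   the part of `s` not explained by baseline and reference — is carried
   inside the corrected spectrum; it is the chemical information.  A
   first-order polynomial baseline is the default (`poly_order=1`); the
   basis uses `ν̃` rather than raw cm⁻¹ values purely for conditioning
   (raw values near 10³ make the normal equations needlessly
   ill-conditioned; the reported `c` is per unit `ν̃`).  `|b| ≤ 1e−6` is
   treated as a failed correction and raises.

2. **Second derivative**, Savitzky–Golay filter with a 15-point window and
   third-order polynomial, computed per spectrum.  Derivatives are taken
   with respect to wavenumber (divided by the grid spacing squared, units
   a.u.·cm²), so results do not silently change when spectra are resampled.
   Edges use the standard polynomial-fit handling (`mode="interp"`), which
   keeps the point count constant across stages — downstream models need
   fixed dimensionality.  Note the filter's smoothing bias: the estimate of
   a Gaussian band's center curvature −A/σ² is accurate only when the
   window half-width is small relative to σ (at 2 cm⁻¹ spacing the 15-point
   window spans ±14 cm⁻¹, which biases the curvature of a σ = 12 cm⁻¹ band
   by roughly 27%; at 0.25 cm⁻¹ spacing the bias is ~0.4%).  This bias is a
   property of all SG-derivative preprocessing and is harmless here because
   every spectrum passes through the same filter.

3. **Mean-centering** by the column mean of the fitting set's
   second-derivative spectra.

Every parameter (EMSC reference, centering mean) is estimated from an
explicit fitting set and applied unchanged elsewhere.  All cross-validation
loops refit the full pipeline inside each fold, so held-out spectra can
never influence their own preprocessing; tests assert bit-identical fold
parameters under held-out perturbations.

Peak-intensity analysis deliberately uses a different representation:
EMSC-corrected, offset-corrected (absorbance at 1800 cm⁻¹ subtracted),
*non-derivative* spectra, because diagnostic-peak intensities are absorption
maxima, not derivative minima.

## Univariate peak statistics

Twelve literature-anchored diagnostic bands (1663, 1630, 1580, 1456, 1414,
1315, 1121, 1086, 1041, 925, 855, 780 cm⁻¹) are quantified as the maximum
absorbance in a ±8 cm⁻¹ window (tolerating small drift while keeping the
1041/1086 windows disjoint), one value per replicate spectrum.  Association
with PMI uses replicate-level pairs (20 samples × 4 replicates = 80
observations): Pearson r, 95% CI by Fisher's z-transformation
(`tanh(atanh r ± z₀.₉₇₅/√(n−3))`), two-sided t-test p-values (df = n−2),
Benjamini–Hochberg FDR over the 12-band family, and qualitative labels
(Strong |r| ≥ 0.5, Moderate ≥ 0.4, Weak below; "Not significant" when the
adjusted p ≥ 0.05).  Replicates are treated as independent observations —
no within-sample clustering correction — and every result object carries
that caveat explicitly; with 4 replicates per donor the CIs are
anti-conservative at the donor level.

## Multivariate models

**PCA** is computed by SVD of the centered sample-level matrix (replicate
means of preprocessed spectra), variance ratios with n−1 denominators.

**PLS** is single-response NIPALS, which is deterministic: `w ∝ X'y`,
`t = Xw`, `p = X't/t't`, `q = y't/t't`, deflate `X`, and
`B = W(P'W)⁻¹q`.  Requesting more components than the data's rank truncates
with a warning.  With A = rank, NIPALS reproduces the least-squares solution
(asserted in tests); predictions from sklearn's `PLSRegression` are used as
an independent cross-check in the test suite only.

**VIP** scores use `VIP_j = √(P · Σₐ SSₐ (w_ja/‖wₐ‖)² / Σₐ SSₐ)` with
`SSₐ = qₐ² tₐ'tₐ`; the mean of squared VIPs is identically 1, asserted for
every fitted model.  **Standardized coefficients** are `B_j·sd(X_j)` (hours
per predictor SD).  Their 95% bootstrap bands resample samples with
replacement (100 draws, percentile method); bootstrap draws are rescaled by
the *full-sample* column SDs, not each resample's own, so the band reflects
model uncertainty rather than resampling noise in the scale itself
(otherwise the band width has a floor of ≈ |B|/√(2n) even for noiseless
data).  Degenerate resamples (constant response) are redrawn and counted.

**Hierarchical clustering** of preprocessed spectra uses Ward linkage on
Euclidean distances (scipy); these defaults are package conventions.

## Validation and uncertainty

* **Repeated splits**: five random 75/25 splits; per split the component
  count A ∈ 1..10 (capped at n_train−1) is chosen by LOOCV RMSECV on the
  training set, ties to the smallest A; the test set is scored once.
* **Final model**: A = 2, calibrated on all known samples, assessed by
  LOOCV with full pipeline refits; RMSE/MAE/R².
* **Residual diagnostics**: Shapiro–Wilk normality and Brown–Forsythe
  (median-centered Levene) homoscedasticity, groups split at the median
  predicted value (the grouping is a package convention).
* **Percentile intervals**: the 50th/75th/90th percentiles of absolute
  LOOCV errors give symmetric intervals around each prediction.
* **95% half-width**: non-parametric bootstrap of the LOOCV residual vector
  (1000 resamples); each replicate contributes the 95th percentile of
  absolute residuals and the half-width is the mean over replicates.  The
  aggregation functional is not uniquely determined by the procedure's
  description; `median` and `percentile` (95th percentile of replicates,
  more conservative) are available behind a keyword.
* **Consistency rule**: an external estimate is `consistent_k` for the
  tightest percentile interval k containing it, `discrepant` outside the
  90% interval, and `large_discrepancy` when the gap also exceeds the 95%
  half-width — the signature of biochemical age decoupling from
  chronological time (prolonged refrigeration).  Interval bounds are
  rounded to whole hours (halves away from zero) only at render time.
* **Reliability tiers** for calibration samples: absolute LOOCV error
  below RMSE → reliable, within [RMSE, 2·RMSE] → borderline (boundaries
  inclusive), beyond → problematic.

## Triage classification

Early (PMI ≤ 48 h, boundary inclusive) versus late classification with five
untuned classifiers on the same preprocessed sample-level matrix: Random
Forest (500 trees, √P features per split, unlimited depth, seeded), LDA,
QDA, and linear/RBF SVM (C = 1, bandwidth 1/(P·Var)).  Full-covariance QDA
is singular at P ≫ n, so QDA runs with diagonal class covariances shrunk
0.5 toward their mean variance (flagged in output).  Confusion metrics come
from LOOCV with per-fold pipeline refits; undefined precision (no predicted
positives) is reported as 0 by convention.  The final Random Forest is
refit on all known samples; query-sample confidence is the tree-vote share
(≥ 0.5 by construction), and Gini importances are normalized to sum 1.
Query samples stored under prolonged refrigeration have their
agreement-with-estimate annotated with a biochemical-age caveat rather than
taken at face value.

With C = 1 on second-derivative features of magnitude ~10⁻⁴, the SVMs
underfit and predict the majority class (early precision/recall 0) — this
is reproduced deliberately, as it is the documented behaviour of untuned
SVMs in this setting, not a defect.

## Regression method comparison

PLS (2 components), OLS, Huber, Theil–Sen and RANSAC are compared by LOOCV
on four cohort variants: all known samples; excluding flagged clinical
confounders; excluding samples the PLS model itself marks problematic
(error > 2·RMSE); and the forensic PMI < 72 h subset.  A variant with
fewer than 5 samples is refused.  OLS uses the minimum-norm solution when
P ≥ n.  Theil–Sen's median-of-slopes estimator is undefined at P ≥ n; the
fit falls back to OLS and sets an explicit flag (so identical
Theil–Sen/OLS rows in reports are self-explaining).  RANSAC uses minimal
subsets of 3 on the spectra directly, residual threshold = the median
absolute deviation of y, seeded.  Huber non-convergence is flagged rather
than raised.

## Synthetic cohort generator

Because case spectra cannot be redistributed, every stage is exercised on a
generator that emulates the study design: `n_known = 20` calibration
samples (documented PMI over 24.8–97.6 h), `n_unknown = 10` query samples
with scene estimates (true PMI × uniform ±30% error), 4 replicates per
sample.  PMI values are drawn stratified-uniform (one draw per equal-width
stratum), emulating a cohort selected to cover the range evenly — the
marginal distribution is uniform, but degenerate clustered cohorts that a
small iid draw occasionally produces are excluded by design.

Spectra are sums of Gaussian bands: the 12 diagnostic bands plus 6
non-diagnostic filler bands (widths 7–10 cm⁻¹, base intensities
0.06–0.40 a.u.).  Band amplitude for sample s is
`μ_j + β_j·PMI_eff + δ_js`, with `δ_js ~ N(0, 0.005 a.u.)` a band-specific
between-sample effect.  Slopes `β_j` are calibrated so replicate-level
peak–PMI correlations have prescribed magnitudes spanning |r| ≈ 0.02–0.55
(strong carbohydrate/phosphate trends, near-null nucleic-acid band):
`β_j = r_j/√(1−r_j²) · sd_eff/sd(PMI)` with
`sd_eff = hypot(sample_sd, replicate_noise_sd)`.

Each replicate is observed as `b·clean + a + c·ν̃ + ε`: log-normal scatter
(`ln b ~ N(0, 0.05)`), additive offset (`a ~ N(0, 0.02 a.u.)`), baseline
tilt (`c ~ N(0, 0.01 a.u.)`) and white per-point noise
(`ε ~ N(0, 0.015 a.u.)`, covering film repositioning and detector noise).
The artifacts lie exactly in the EMSC model space, so EMSC removes them
without touching chemistry — at zero replicate noise, corrected artifacted
spectra equal corrected clean spectra to numerical precision (a test).
Noise was deliberately left white rather than instrument-band-limited:
smooth noise passes the SG derivative filter the way chemical bands do and
is the more hostile, less informative choice for testing recovery.  All
randomness derives from per-sample substreams of one seed, and every
random quantity is drawn as a standard deviate scaled afterwards, so
configs differing only in dispersion parameters share their draws (matched
artifact-on/off cohorts).

Injectable confounders: `protein_shift` and `carb_shift` rescale band
amplitudes in 1700–1500 / 1180–955 cm⁻¹ (pathology-like profiles),
`refrigerated` regenerates a sample at effective PMI = true PMI × 0.45
(default retardation factor; a 179 h case maps to ≈ 80.6 h of biochemical
age).  Ground truth (true and effective PMI, band amplitudes, artifact
parameters, clean spectra) is returned alongside the cohort for
oracle-style tests.

**What passing tests show, and what they do not.**  The generator is linear
in PMI with Gaussian bands and homoscedastic effects; real vitreous-humor
kinetics are nonlinear, temperature-dependent, and biochemically coupled
across bands.  Synthetic recovery results (e.g. 2-component PLS LOOCV R²
typically 0.69–0.81 across seeds at default noise) validate the
*machinery* — leakage-free preprocessing, component selection, interval
construction — not the field performance of FTIR PMI estimation, which
only case data can establish.

## Problem sizes and defaults

Default grid 1800–700 cm⁻¹ at 2 cm⁻¹ spacing (551 points; recording
resolution is 4 cm⁻¹ but post-FT point spacing is finer, and half-integer
feature positions require ≤ 2 cm⁻¹).  The full pipeline (simulation,
preprocessing, peak statistics, PCA, 5 splits with component selection,
LOOCV, 100-draw coefficient bootstrap, 1000-draw interval bootstrap,
5-classifier triage LOOCV, 5 × 4 method comparison) runs in well under a
minute on one CPU; the test suite uses the same sizes throughout.

## Known limitations

* Replicate pseudo-replication in the univariate CIs (see above).
* The consistency rule's `large_discrepancy` threshold (95% half-width)
  can fire for any sufficiently wrong scene estimate, not only
  refrigeration artifacts; the storage flag, not the label, identifies the
  mechanism.
* EMSC division by the fitted `b` makes corrected intensities a mildly
  nonlinear (ratio-linear) function of PMI even for perfectly linear band
  kinetics; with the default calibration this contributes < 1 h of LOOCV
  RMSE in the noiseless limit.
* No atmospheric (CO₂/water-vapor) correction and no support for vendor
  binary formats; inputs are wide CSV tables.
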