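# Methods

## The statistical model

The LA acceleration factor `α = v_E / ((v_S + v_D)/2)` is treated as
a linear correlate of mean pulmonary artery wedge pressure (PAWP).
Three linked analyses operationalise this:

1. **Model selection.** Any ratio of a linear combination of the two
   outflow peaks to a linear combination of the two inflow peaks can,
   up to an overall constant absorbed by the regression slope, be
   written `α_general = (v_{E+A} + c_out·v_{E−A}) / (v_{S+D} +
   c_in·v_{S−D})` with half-sum/half-difference velocity
   combinations. Non-linear least squares of
   `PAWP_i = β0 + β1·α_general(q_i; c_out, c_in) + ε_i` estimates the
   ratio constants; the specific form α (i.e. `c_out = 1`, `c_in = 0`)
   is accepted as optimal when both constants' 95% confidence
   intervals contain those values. A variant fixes `c_out = 1`
   (collapsing the numerator to `v_E`) so patients without a late
   diastolic peak can be included.
2. **Calibration.** OLS of α on PAWP, `α = a + b·PAWP`, with Pearson
   r, RMSE, and the leave-one-out PRESS R²; inversion
   `PAWP_calc = (α − a)/b` yields a non-invasive PAWP estimate whose
   agreement with the measured PAWP is summarised by Bland-Altman
   bias and limits of agreement (bias ± 1.96·SD of differences).
3. **Diagnosis.** ROC analysis of α for PAWP > 15 mmHg (and, within
   PH patients, for post-capillary PH). The working cut-off is the
   calibration line evaluated at the threshold, `a + b·15`; the
   Youden cut-off (maximal sensitivity + specificity, lowest
   threshold on ties) is reported alongside. Positivity is strict
   (`α > cut-off`), which makes the regression cut-off rule exactly
   equivalent to `PAWP_calc > 15`.

## Numerical choices

* **Ratio-constant estimation.** The intercept/slope enter linearly,
  so they are profiled out (a 2×2 least-squares solve inside the
  residual function) and only the ratio constants are optimised, by
  trust-region least squares from the multi-start grid
  {0, 0.5, 1} × {−0.5, 0, 0.5, 1}; steps producing a non-positive
  denominator are rejected. Confidence intervals are classical
  large-sample Wald intervals, `estimate ± t_{0.975,n−p}·SE` with
  covariance `s²(JᵀJ)⁻¹` from the analytic full-parameter Jacobian at
  the optimum (p = 4 free, 3 with `c_out` fixed). The construction
  was cross-checked against `scipy.optimize.curve_fit`. The
  "non-linear correlation coefficient" is `√(1 − SSE/SST)`.
* **PRESS** uses the hat-matrix identity `e_i/(1 − h_ii)`, verified in
  tests against explicit refit-without-i predictions.
* **Group comparison**: one-way ANOVA plus Tukey-Kramer adjusted
  pairwise p-values (statsmodels; exact for unequal group sizes).
* **Dependent correlations** (α vs a location variant, sharing PAWP):
  Williams' t with the determinant-of-correlation-matrix form on
  n − 3 df. Identically correlated comparison variables (r_yz = 1
  with r_xy = r_xz, e.g. z a positive affine image of y) return
  t = 0, p = 1; other collinear cases are rejected. Steiger-type
  alternatives exist but are not implemented.
* **AUC** is the midrank Mann-Whitney statistic; its CI is DeLong's.
  Sensitivity/specificity get exact Clopper-Pearson intervals (e.g. a
  13/14 sensitivity spans 66–100%). ROC thresholds are midpoints of
  consecutive distinct scores with ±∞ sentinels.
* **One-sample t** on zero-variance input: all-zero differences give
  (0, 1); constant non-zero differences give (±∞, 0) by sign.
* Degenerate inputs fail loudly: zero PAWP variance, single-class ROC
  labels, mismatched pair lengths, rank-deficient partial-F designs.

## The synthetic-data generator

The generator's defaults are the study conditions; they are not meant
to be tuned per analysis.

| Parameter | Default | Meaning |
|---|---|---|
| group sizes | 28 / 21 / 13 | non-PH / pre-capillary / post-capillary PH |
| PAWP (mmHg) | 8±4, 10±4, 18±3 | group truncated normals |
| truncation | (0, 15], (0, 15], (15, 28] | keeps group labels concordant with the 15 mmHg rule |
| `alpha_intercept`, `alpha_slope` | 0.61, 0.10 /mmHg | planted calibration law |
| `alpha_noise_sd` | 0.20 | residual scatter of α, ≡ 2.0 mmHg on the PAWP scale |
| v_S (cm/s) | 39±11 / 32±10 / 24±14 | group-conditional; encodes the negative v_S–PAWP correlation |
| v_D (cm/s) | 33±9 / 33±9 / 31±9 | nearly PAWP-independent |
| v_A (cm/s) | 38±10 / 39±16 / 42±27 | latent-factor correlated with v_S (r = 0.58 within group) |
| `rho_vs_vd` | 0.38 | v_S–v_D correlation |
| `monophasic_fraction` | 6/62 | Bernoulli per patient; v_A (and v_A,tip) missing |
| vein split | 25:37 left:right | label only, no distributional effect |
| tip/vein velocities | 35±11 (r .73), 34±10 (r .44), 60±19 (r .88), 40±17 (r .81) | conditional bivariate draws against the pooled-standardised junction velocity |

Noise enters on the α scale and `v_E = α_true·(v_S+v_D)/2` is derived,
which automatically reproduces the opposite signs of the v_E–PAWP and
v_S–PAWP associations. Positivity of all velocities (and of α_true)
is enforced by deterministic rejection sampling (≤1000 redraws under
the seed). The tip/vein velocities are drawn conditionally with their
own marginal mean/SD and correlation, which jointly implies the
observed location biases (e.g. v_E,tip − v_E = 6 ± 9 cm/s); a purely
additive bias+noise model cannot match marginals, correlations and
difference SDs simultaneously.

Two structural consequences are worth knowing:

* The **pooled** v_S–v_A correlation is ≈0.41, attenuated from the
  within-group 0.58 because the group means of v_S fall while those
  of v_A rise.
* Because v_S (and through it v_A) carries PAWP information beyond
  the planted α law, the population least-squares optimum of the
  PAWP-on-ratio regression is displaced from the planted (1, 0) to
  roughly (0.90, 0.07). Replicate estimates therefore centre there,
  and 95% Wald intervals cover the planted constants at ≈80–82% per
  constant rather than nominally — while still containing (1, 0) in
  the single-cohort analyses, the same qualitative picture the
  original intervals show (centred near 0.84 and 0.14 yet containing
  1 and 0). This displacement is a property of the data-generating
  structure, not of the fitting code.

**Waveforms** are sums of raised-cosine bumps on a zero baseline:
venous S and D bumps at fractions 0.20 and 0.55 of the RR interval,
transmitral E and A bumps at 0.55 and 0.85, half-width 0.10, sampled
at 20 cardiac phases of an 800 ms RR interval (HR 75, within the
cohort's range). Default peak times lie on sample points, so peak
detection inverts generation exactly at zero noise; overlapping bumps
(which would hide a planted maximum) are rejected. **Toy 4D fields**
plant Gaussian-profile jets (σ = 1.2 voxels) through one-voxel-thick
axis-aligned planes — a moving mitral plane and two fixed vein
planes — with per-phase in-plane maxima equal to the waveform
samples; the non-selected vein is scaled to 85%. The default
VENC-like bound is 90 cm/s and is raised per patient when a planted
jet would exceed it, mirroring per-scan adaptation; with adaptation
disabled, exceeding it is an error.

**Peak extraction** uses phase windows (fractions of RR from the
R-wave): systole [0, 0.40) for v_S, early diastole [0.40, 0.75) for
v_E and v_D, late diastole [0.75, 1.0) for v_A. Windows are
configurable; ties go to the earliest sample. v_A additionally
requires a local maximum with prominence ≥ 10% of the curve maximum —
otherwise the profile is called monophasic. The prominence threshold
has no external reference value; 10% was chosen once as a scale-free
rule that cleanly separates the generator's biphasic and monophasic
waveforms (records whose true v_A falls below it are counted, not
errors). Vein selection takes the curve with the larger overall
maximum, ties to the right vein.

## What the simulations do and do not show

Passing tests demonstrate that the statistical machinery is correct
(against independent oracles: exhaustive pair counting for AUC,
explicit leave-one-out refits for PRESS, manual extra-sum-of-squares
algebra, permutation distributions, the two-group Tukey/t identity)
and that the pipeline reproduces the study's headline numbers *under
the planted model*: replicate means r ≈ 0.94, slope 0.10, intercept
0.61, SD of differences ≈ 2.0 mmHg, cut-off ≈ 2.11, mean α ≈ 1.67.
They do not validate the physiological claim on real data: the
generator imposes exact within-group normality, a perfectly linear
α–PAWP law with homoscedastic noise, stylised single-jet flow fields
without vortices, stasis, aliasing, eddy-current or background-phase
effects, and concordant group labels (no borderline patients with
mPAP 21–24 mmHg). Simulated diagnostic accuracy (replicate-mean AUC
≈ 0.985) modestly exceeds the single-cohort value 0.97, as expected
when the model is exactly true.

## Problem sizes

Default analyses use the 62-patient cohort. Monte-Carlo summaries in
tests use 200–500 replicate cohorts and the acceptance script uses
500; waveforms use 20 phases and toy fields a 24×24×12 grid —
choices that keep full runs in the seconds-to-a-minute range while
leaving Monte-Carlo error well below the assertion tolerances.

## Known limitations

* Only five pairwise velocity correlations are constrained; the full
  joint distribution is one admissible latent-factor structure.
* Wald (not profile-likelihood) intervals for the ratio constants;
  at n ≈ 56 with this curvature they are adequate but not exact.
* The CLI's `extract` path regenerates waveforms from the cohort CSV
  rather than ingesting scanner data; no DICOM/real 4D-flow support.
* mPAP, PVR and TPG are not simulated; PH-group membership is a
  label, so analyses conditioned on haemodynamics other than PAWP are
  out of scope.
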