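# laflow

Non-invasive estimation of mean pulmonary artery wedge pressure (PAWP)
from the **left-atrial (LA) acceleration factor**, a dimensionless
ratio of 4D-flow-derived LA peak outflow to peak inflow velocities —
implemented as a fully synthetic, seeded simulation-and-analysis
pipeline.

## The problem

PAWP, measured by right heart catheterization (RHC), is the surrogate
for mean LA pressure that separates pre-capillary from post-capillary
pulmonary hypertension (PH) at the 15 mmHg threshold. Because LA
pressure both drives transmitral outflow and brakes pulmonary-venous
inflow, the ratio of LA peak outflow to inflow velocities should rise
with PAWP. From time-resolved, three-directionally velocity-encoded
(4D flow) MR data one can read four peak velocities:

* `v_S`, `v_D` — systolic / early diastolic LA peak **inflow**
  velocities at the pulmonary-vein orifices,
* `v_E`, `v_A` — early / late diastolic LA peak **outflow**
  (transmitral) velocities.

The LA acceleration factor is

```
α = v_E / [(v_S + v_D)/2]
```

Its form is selected from the general ratio family
`α_general = (v_{E+A} + c_out·v_{E−A}) / (v_{S+D} + c_in·v_{S−D})`
(half-sum/half-difference notation) by non-linear least squares of
PAWP on the four velocities: the choice is optimal when `c_out = 1`
and `c_in = 0` lie inside the large-sample 95% confidence intervals.
A linear calibration `α = a + b·PAWP` is then fitted, inverted to
`PAWP_calc = (α − a)/b`, and evaluated by Bland-Altman agreement and
ROC analysis of the rule `α > a + b·15` for detecting PAWP > 15 mmHg.

No patient data are distributed. The package's synthetic-cohort
generator reproduces the study conditions — three groups (28 non-PH /
21 pre-capillary PH / 13 post-capillary PH) with truncated-normal
PAWP (8±4, 10±4, 18±3 mmHg), group-conditional velocity
distributions, the planted law `α = 0.61 + 0.10·PAWP` with residual
SD 0.20, a 6/62 monophasic-transmitral fraction, and
alternative-location (mitral-tip / intra-vein) velocities — so every
stage, from waveform peak detection on toy 4D velocity fields to the
final ROC curve, is testable end to end.

## Worked example

```sh
laflow run --seed 1 --out demo/
```

prints

```json
{
  "auc": 0.967032967032967,
  "cutoff_regression": 2.092353065282168,
  "r": 0.9363792887978202,
  "sd_diff_mmHg": 1.7580991313079468
}
```

and writes `demo/report.json`, `demo/cohort.csv` and
`demo/roc_points.csv`. Reading: on this 62-patient synthetic cohort α
correlates with PAWP at r = 0.94; the fitted line maps the 15 mmHg
threshold to the α cut-off 2.09; inverting the regression
back-calculates PAWP with an error SD of 1.8 mmHg; and α discriminates
elevated PAWP with AUC 0.97. The full report also contains the
general-ratio fit (here `c_out` = 0.90 with 95% CI 0.69–1.12 and
`c_in` = 0.06 with CI −0.09–0.22, so the α form is accepted as
optimal), the group comparison (Tukey-Kramer), and the
measurement-location analysis (one-sample t-tests on tip/vein
velocity biases, Williams-Hotelling tests showing the junction-based
α correlates with PAWP more strongly than α_tip, α_vein or
α_tip/vein).

Monte-Carlo mode summarises the sampling distribution of every
headline statistic:

```sh
laflow replicate --seed 1 --replicates 200 --out replicates.csv
```

The same functionality is available from Python:

```python
from laflow import CohortConfig, RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=1))
report["calibration"]["r"]          # 0.936...
```

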