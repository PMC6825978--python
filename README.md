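# dasikit

Survival estimation for cancer patients at the time of an **unplanned
hospitalization**, built around a **deficit-accumulation survival index
(DASI)** and the 30-day unplanned readmission flag as prognostic signals.

Tumor stage and histology say little about short-term survival once disease
is advanced; what does carry signal at the moment of an unplanned admission
is the accumulated burden of small, individually weak deficits — abnormal
admission labs, inflammation ratios, malnutrition markers, performance
status, utilization history. `dasikit` is a library (plus a thin `dasi` CLI)
for clinical researchers who want to score such cohorts, fit the associated
survival models, and stress-test the whole workflow on synthetic data with a
known generative truth.

## The index and the models

For each patient, 23 prespecified binary deficits are evaluated
(`d_k ∈ {0,1}`: e.g. sodium < 135 mmol/L, corrected calcium ≥ 11 mg/dL,
NLR > 5, ECOG ∈ {2,3,4}, 30-day readmission, metastasis, …) and

```
DASI = (1/23) Σ d_k            ∈ [0, 1]
```

banded into low (≤ 0.30), moderate (0.30–0.48] and high (> 0.48) risk. The
cutoffs live in a YAML registry (`dasikit/data/factors.yaml`) so sensitivity
analyses can vary them; the composite inputs are

```
NLR = neutrophils / lymphocytes        PLR = platelets / lymphocytes
SII = PLR × neutrophils                PNI = albumin × lymphocytes
```

(the PNI here is the literal albumin–lymphocyte product; the conventional
Onodera form `10·albumin + 5·lymphocytes` is available via
`pni_convention="onodera"`).

Survival machinery: Kaplan–Meier product-limit curves with Greenwood
variance and Brookmeyer–Crowley-style median CIs (log(−log) band), K-group
log-rank tests, and Cox proportional-hazards regression maximizing the
partial likelihood by Newton–Raphson (Efron tie handling by default, Breslow
optional, Wald inference, score test at β = 0). Model building follows a
prespecified recipe: univariate screen at p < .05, a collinearity rule that
carries only NLR out of the correlated inflammation-marker block, forced
covariates regardless of significance, and an overfitting budget of 13
covariates. Robustness to missing data comes from chained-equations multiple
imputation (predictive mean matching; m = 20 by default) with the focal
hazard ratio reported as a min–max range and a Rubin's-rules pooled
estimate. Power planning uses Schoenfeld's events formula,
`ln(HR) = (z₁₋α/₂ + z_pow) / √(d·a·(1−a))`.

Because the underlying patient records are not public, the package ships a
generative model (`dasikit.synthetic`) that emulates the study conditions —
a ~270-patient two-arm cohort, moment-matched lab marginals, realistic
missingness, and proportional-hazards survival driven by the *true*
generated deficit score — so every estimator can be validated by parameter
recovery.

## Worked example

```python
from dasikit import cox_fit, km_fit, logrank_test, min_detectable_hr
from dasikit.synthetic import default_paper_config, generate

df = generate(default_paper_config(seed=7)).to_dataframe()
```

Running `examples/simulate_and_fit.py` (which continues exactly this
snippet) prints:

```
n=270, readmitted 43.0%, deaths 40.0%
   control: n=154, events=40, median not reached
readmitted: n=116, events=68, median 225 d
log-rank chi2=31.42 (df=1), p=2.1e-08
readmission HR 2.92 (95% CI 1.97-4.32)
minimum detectable HR at 80% power: 1.72
```

Read: in this simulated cohort the readmitted arm reaches its median
survival at 225 days while the control arm never falls below 50% survival
within follow-up; readmission roughly triples the death hazard, and with
~108 events anything below HR ≈ 1.7 would be underpowered. The other
scripts in `examples/` show single-patient scoring (`score_a_patient.py`)
and the full screen → multivariable model → imputation pipeline
(`full_pipeline.py`, also available as `dasi run --simulate default --seed 11
--out-dir report/`).

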