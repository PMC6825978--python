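# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the synthetic-data generator does and does
not emulate, and the places where the design was genuinely open.

## The deficit-accumulation index

The index follows the Rockwood accumulation-of-deficits principle: many
weak, binary adverse signals are summed and normalized rather than weighted.
Twenty-three factors are registered (demographics and support, utilization,
performance status, anthropometry, admission labs, derived inflammation and
nutrition indices, readmission and metastasis), each with a fixed adverse
cutoff. The score is the deficit sum divided by the number of factors, so it
lives in [0, 1] and is monotone: flipping any factor from absent to present
can only raise it.

**Cutoff convention.** A deficit fires only when the adverse rule matches
literally. All cutoffs are strict inequalities except corrected calcium,
whose adverse rule is inclusive (≥ 11 mg/dL); values exactly at a strict
boundary (sodium = 135, NLR = 5, 2 prior visits, …) score 0. Fall-risk
"universal" and "low" are non-deficits (only "high" is adverse). The
registry is data (YAML with a provenance checksum), not code.

**Risk bands.** The published band definitions are internally inconsistent
at the first boundary (low described both as "< 0.30" and "< 0.31"). We use
the contiguous partition low ≤ 0.30 < moderate ≤ 0.48 < high so that every
score in [0, 1] is classifiable; the property suite enforces totality and
contiguity.

**Missing factors.** The literal construction rule divides by 23 regardless
of missingness (`fixed_23`, the default), which means a missing factor can
only lower the score — conservative in the direction of under-calling risk.
The standard frailty-index convention of dividing by the evaluable count
(`evaluable`) is also implemented. Either way a score is only reported when
at least 18 of 23 factors (~78%) are evaluable; below that the patient is
unscored rather than misleadingly scored. The floor is configurable.

**PNI.** The prognostic nutrition index is implemented as the literal
product albumin × lymphocytes, with the conventional Onodera form
(10·albumin + 5·lymphocytes) behind a flag. Note the product form with
albumin in g/dL yields values of order 1–10, so the < 45 cutoff classifies
nearly every realistic patient as deficient; the published summary
statistics for PNI (mean ≈ 42.5) are only consistent with the Onodera-like
scale. We keep the literal product as the default because the methods text
defines it that way, and document that under the default this factor is
near-constant; analysts who want a discriminating PNI factor should switch
the convention or adjust the cutoff in the registry.

## Survival estimation

**Kaplan–Meier.** Product-limit estimation is delegated to lifelines; the
wrapper adds the Greenwood variance computed from the event table, the
median defined as the smallest event time with S(t) ≤ 0.5, and a median CI
obtained by inverting the pointwise log(−log) confidence band
(Brookmeyer–Crowley style). A band that never crosses 0.5 yields an
"undetermined" bound, which is propagated to reports as text rather than a
number.

**Cox regression.** The partial likelihood is maximized by Newton–Raphson
with analytic gradient and Hessian, implemented in-package because the
analysis needs Breslow as well as Efron tie handling, access to the score
test at β = 0, and explicit degeneracy diagnostics. Efron is the default:
survival times are recorded at day resolution, so ties are the norm.
Convergence requires max |score| < 1e-6 or a relative log-likelihood change
< 1e-9, within 100 iterations, with step-halving to guarantee ascent.
Monotone likelihoods (complete separation) are detected two ways — a
coefficient passing |β| > 20 during iteration, or |β| > 10 at convergence —
and raise a diagnostic error instead of returning a silently huge hazard
ratio. Rank-deficient designs are rejected before fitting, naming the
collinear columns via pivoted QR. Wald inference throughout (HR = e^β, 95%
CI = e^{β±1.96·SE}); the linear predictor is max-shifted before
exponentiation for overflow safety. The test suite cross-checks
coefficients, standard errors and log-likelihood against lifelines, the
score test against the log-rank statistic (an exact identity for Breslow
ties, two groups, untied times), and the estimate against brute-force
likelihood maximization on a small fixture.

**Model building.** The univariate screen fits one Cox model per registered
covariate on complete cases, selecting at Wald p < .05. Right-skewed markers
(corrected calcium, creatinine, NLR, neutrophils, PLR, platelets, SII, WBC)
enter as natural logs; length of stay as log(x+1) because zero-day stays
occur. Categorical covariates expand to indicator contrasts against fixed
reference levels (lung for cancer type, pain for admission reason, married,
English, white, high fall risk, ECOG 0, DASI low). The multivariable model
takes all screen selections, collapses the highly correlated inflammation
block {NLR, neutrophils, PLR, platelets, SII} to its representative (NLR),
and force-includes readmission (the exposure), cancer type and prior
health-care utilization regardless of significance. The overfitting budget
of 13 is counted in **covariates** (model variables), not expanded indicator
terms — a 10-level cancer-type factor inside a 9-variable model is exactly
the situation the budget was meant to allow. The DASI band is screened and
reported but never entered into the multivariable model, since it is a
deterministic function of the other covariates. The pipeline, by default,
trims screen selections beyond the budget largest-p-first (recorded in the
report notes); calling `build_multivariable` directly with an over-budget
selection raises instead.

**Power.** The minimum detectable hazard ratio uses Schoenfeld's events
formula. The published minimum detectable HRs (1.54 for readmission, 1.69
for the index) do not reproduce from the published sample size, event count
and allocation under this standard formula for any plausible reading; the
implementation documents the formula it uses rather than reverse-engineering
undisclosed assumptions, and the acceptance script reports the value the
formula actually gives (~1.7 at ~110 events, balanced arms).

## Multiple imputation

Chained equations with 10 cycles per dataset: predictive mean matching
(5 donors) for numeric covariates, proportional draws from the observed
level frequencies for categorical ones. The outcome is never imputed and
always predicts (log time and the event indicator). Observed cells are never
modified; a complete frame passes through unchanged, and runs are
bit-reproducible given the seed. The focal covariate's hazard ratio is
summarized primarily as the min–max range across the m = 20 refits (an
assumption-light summary) alongside the Rubin's-rules pooled estimate
(pooled coefficient; total variance = within + (1+1/m)·between).

## The synthetic generator

The generator emulates the study conditions: n = 270 with readmission
probability 0.504; lab marginals as lognormal laws moment-matched to the
published summaries (mean/SD for near-symmetric labs like sodium and
albumin, mean/median for the heavily right-skewed ones like lymphocytes and
WBC — the mean≫median pattern is what motivates the lognormal family);
categorical marginals (marital status, fall risk, ECOG, metastasis, cancer
type, admission reason) at their published frequencies; per-field MCAR
missingness at the published missing counts; administrative censoring at
426 days plus a 30% staggered-entry-style uniform censoring fraction.

Dependence is induced by a Gaussian copula with a single shared latent
severity factor (loading ρ = 0.3 by default, 0 for independence tests), each
variable oriented so that higher severity is more adverse. Deficits are
**not** drawn as free bits: the observables are generated first and the true
DASI score is computed from them by the package's own scoring rules, so
derived-index deficits (NLR, PLR, SII, PNI, BMI) are automatically coherent
with their inputs. Survival then follows the proportional-hazards model
h(t|x) = λ₀·exp(β_r·readmission + β_d·score) with exponential baseline
(Weibull available). Defaults β_r = ln 2 (consistent with the reported
1.8–2.0 imputation range for the readmission HR) and β_d = 5 per unit score
(so the ~0.3-score gap between the low and high bands corresponds to a
hazard ratio of about e^1.5 ≈ 4.5, the observed order of magnitude). λ₀ =
1.3×10⁻⁴/day was calibrated once, numerically, so that ~41% of patients die
before censoring under the defaults, matching the published vital-status
margin; it is frozen as a constant. Times are floored to whole days (ties
are realistic; a recorded time equal to the horizon is always a censoring).

What the generator does **not** emulate: inter-lab correlation beyond the
single shared factor, matched-pair control sampling by admission date,
informative (outcome-dependent) missingness, and any within-patient
longitudinal structure. Passing parameter-recovery tests therefore shows the
estimators are correct under MCAR, proportional hazards and this dependence
structure — not that the pipeline is robust to violations of them.

`recovery_config` provides a deliberately clean design (independent
variables, β_d = 0, two equal arms, ~40% events) in which the marginal and
conditional readmission effects coincide, used for unconfounded parameter
recovery and CI-coverage checks.

## Problem sizes used in the checks

The automated checks run the default n = 270 pipeline end-to-end (with the
full m = 20 imputation), one n = 2000 recovery fit, 200 replicates of n = 500
for CI coverage, 200 replicates of n = 150 for screen calibration, and an
exhaustive 70-split permutation null at n = 8 — sizes chosen to make
stochastic tolerances tight (binomial ±3.5–5 points) while each suite stays
in the tens of seconds.

## Known limitations

- Complete-case fitting is the primary analysis; imputation is a
  sensitivity analysis, not the headline estimate (mirroring the study
  design the package implements).
- No proportional-hazards diagnostics (Schoenfeld residuals), time-dependent
  covariates, or competing risks.
- The chief-complaint lexicon is a keyword table; free text outside it falls
  into "other" by construction.
- Separation in sparse categorical levels (e.g. a rare cancer type with no
  events on the complete-case subset) is surfaced as a diagnostic error and
  the pipeline records the model as not fitted for that input rather than
  reporting an unstable coefficient.
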