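"""Generate a synthetic cohort and fit the survival models.

Draws a 270-patient cohort from the default generative config (two ~equal
readmission arms, proportional hazards in the readmission flag and the true
deficit score, administrative censoring, realistic missingness), then fits
Kaplan-Meier curves by arm and a univariate Cox model for the readmission
hazard ratio, and evaluates the minimum detectable HR at this event count.
"""

from dasikit import cox_fit, km_fit, logrank_test, min_detectable_hr
from dasikit.synthetic import default_paper_config, generate

cohort = generate(default_paper_config(seed=7))
df = cohort.to_dataframe()
print(f"n={len(df)}, readmitted {df.readmitted_30d.mean():.1%}, "
      f"deaths {df.event.mean():.1%}")

arms = {name: df[df.readmitted_30d == flag] for name, flag in
        [("control", False), ("readmitted", True)]}
for name, arm in arms.items():
    curve = km_fit(arm.survival_time, arm.event)
    med = "not reached" if curve.median is None else f"{curve.median:.0f} d"
    print(f"{name:>10}: n={curve.n}, events={curve.n_events}, median {med}")

lr = logrank_test([(a.survival_time, a.event) for a in arms.values()])
print(f"log-rank chi2={lr.statistic:.2f} (df={lr.df}), p={lr.p_value:.2g}")

fit = cox_fit(df.survival_time, df.event, df.readmitted_30d.astype(float),
              names=["readmission"])
print(f"readmission HR {fit.hazard_ratio[0]:.2f} "
      f"(95% CI {fit.ci_lower[0]:.2f}-{fit.ci_upper[0]:.2f})")
# With ~110 events split ~50/50 the smallest detectable hazard ratio at 80%
# power is around 1.7; observed effects below that line are underpowered here.
print(f"minimum detectable HR at 80% power: "
      f"{min_detectable_hr(int(df.event.sum()), df.readmitted_30d.mean()):.2f}")
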