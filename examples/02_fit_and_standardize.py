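"""Fit the case-mix model and compute standardized hospital risks.

Fits the fixed-effects logistic regression (patient covariates + one effect
per hospital), prints the covariate coefficient table in the usual
estimate/SE/OR/CI layout, and computes each hospital's directly standardized
risk R_h — the fraction of the WHOLE population expected dead or
ADL-dependent at 3 months under that hospital's level of care — with its
delta-method standard error.
"""

import careprofiler as cp

cfg = cp.default_config_riksstroke()
cohort, truth = cp.generate_cohort(cfg, seed=1)
included, _ = cp.apply_inclusion_criteria(cohort)

design = cp.encode_design(included, coding="reference")
y = included.df["outcome"].to_numpy(float)
fit = cp.fit_casemix_model(design, y)

table = cp.coefficient_table(fit, design, y)
covariate_rows = table.iloc[:fit.n_covariate_columns]
print("covariate effects (estimate, SE, OR, 95% CI):")
print(covariate_rows.round(3).to_string())

risks = cp.standardized_risks(fit, design, y)
print(f"\ncrude population risk: {risks.population_risk:.3f}")
print(f"standardized risks R_h: {risks.R.min():.3f}..{risks.R.max():.3f} "
      f"(SE {risks.SE.min():.3f}..{risks.SE.max():.3f})")

ors = cp.hospital_or_vs_average(fit)
print(f"hospital odds ratios vs average: {ors.min():.2f}..{ors.max():.2f} "
      f"({(ors.between(0.8, 1.2)).mean():.0%} within 0.8-1.2)")
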