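"""Classify hospitals with the (delta, k) benchmark decision rule.

The benchmark is B = (1 + delta) x observed population risk: delta encodes
the clinically tolerated relative excess, k the statistical confidence
demanded before flagging. A hospital is outlying when the k-level one-sided
lower confidence bound of its standardized risk exceeds B. The printout
shows how the flagged count shrinks as k grows (more evidence demanded) for
a fixed 10% margin.
"""

import careprofiler as cp

cfg = cp.default_config_riksstroke()
cohort, _ = cp.generate_cohort(cfg, seed=1)
included, _ = cp.apply_inclusion_criteria(cohort)
design = cp.encode_design(included)
y = included.df["outcome"].to_numpy(float)
fit = cp.fit_casemix_model(design, y)
risks = cp.standardized_risks(fit, design, y)

print(f"population risk {risks.population_risk:.3f}")
for delta in (0.0, 0.10, 0.15, 0.20):
    B = cp.benchmark_value(risks.population_risk, delta)
    n_excess = int(cp.gold_standard_labels(risks, delta).sum())
    print(f"delta={delta:<5} benchmark B={B:.3f}  "
          f"hospitals with R_h > B: {n_excess}/{len(risks.R)}")

print("\nflagged counts at delta=0.10 as confidence k rises:")
for k in (0.10, 0.30, 0.50, 0.75, 0.90, 0.95, 0.99):
    dec = cp.classify_hospitals(risks, cp.DecisionConfig(delta=0.10, k=k))
    print(f"  k={k:<5} outlying: {int(dec.outlying.sum()):>2}")
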