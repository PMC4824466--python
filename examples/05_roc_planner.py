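"""Plan a confidence level with the theoretical ROC tool.

Given standardized risks and standard errors (for instance from last year's
profiling round), the planner computes each hospital's probability of being
flagged at every confidence level k under a normal sampling model, and
summarizes them as theoretical sensitivity/specificity — an ROC curve that
lets a policy maker pick k to match the purpose of the comparison without
running any simulation.
"""

import numpy as np

import careprofiler as cp
from careprofiler.rocplan import PlannerInput

# last year's profiling output for ten hospitals
R = np.array([0.18, 0.20, 0.21, 0.215, 0.22, 0.23, 0.24, 0.26, 0.28, 0.31])
SE = np.array([0.030, 0.012, 0.015, 0.020, 0.010, 0.018, 0.025, 0.015,
               0.022, 0.035])

inp = PlannerInput([f"H{i:02d}" for i in range(10)], R, SE, delta=0.10,
                   population_risk=0.22,
                   k_grid=(0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99))
curve = cp.theoretical_roc(inp)

print(f"benchmark B = {curve.benchmark:.3f} "
      f"(truly in excess: {int(curve.truth.sum())}/10 hospitals)\n")
print("   k    sens    spec")
for k, se_, sp in zip(curve.k, curve.sensitivity, curve.specificity):
    print(f"  {k:4.2f}  {se_:.3f}  {sp:.3f}")
print("\nEach row: expected fraction of truly-excess hospitals flagged and "
      "of acceptable hospitals left unflagged if the rule were run at that "
      "k next year under the same risks.")
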