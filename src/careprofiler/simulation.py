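"""Parametric-bootstrap simulation study of the decision rule.

Covariates and hospital assignments are held fixed at the observed data;
binary outcomes are redrawn from the fitted per-patient risks
(y*_i ~ Bernoulli(p_i)). Each simulated data set is analyzed exactly like
the original: the model is refitted (warm-started at the original optimum,
with a Firth fallback should a resample separate), the replicate's own crude
population risk sets its benchmark, hospitals are classified over a
(delta, k) grid, and classifications are scored against gold-standard labels
computed ONCE from the original fit and the original population risk. The
pooled 2x2 tables yield sensitivity, specificity, PPV, NPV and percent
correct per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .casemix import ModelFit, fit_casemix_model
from .decision import (DEFAULT_DELTA_GRID, DEFAULT_K_GRID, DiagnosticSummary,
                       benchmark_value, gold_standard_labels)
from .registry import CohortTable, DesignMatrix, encode_design
from .standardize import one_sided_lower_bound, standardized_risks

__all__ = [
    "SimulationPlan",
    "DiagnosticGrid",
    "simulate_outcomes",
    "run_simulation_study",
    "export_grid",
]


@dataclass
class SimulationPlan:
    """Replicate count, evaluation grids, and seeding for the bootstrap study."""

    S: int = 1000
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    seed: int = 0
    record_per_replicate: bool = False

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not self.delta_grid or not self.k_grid:
            raise ValueError("delta and k grids must be nonempty")


@dataclass
class DiagnosticGrid:
    """Diagnostics per (delta, k) cell plus bookkeeping of the run."""

    cells: dict[tuple[float, float], DiagnosticSummary]
    truth_counts: dict[float, int]
    n_penalized_refits: int
    S: int
    m: int
    delta_grid: tuple[float, ...]
    k_grid: tuple[float, ...]
    per_replicate: pd.DataFrame | None = None

    def summary(self, delta: float, k: float) -> DiagnosticSummary:
        return self.cells[(delta, k)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (delta, k), cell in sorted(self.cells.items()):
            rows.append({"delta": delta, "k": k, **cell.to_dict()})
        return pd.DataFrame(rows)

    def to_table4_frame(self) -> pd.DataFrame:
        """Wide layout: one row per k, a (Sens., Spec.) column pair per delta."""
        data: dict[str, list] = {"k_x_100": [round(k * 100, 6) for k in self.k_grid]}
        for delta in self.delta_grid:
            sens, spec = [], []
            for k in self.k_grid:
                cell = self.cells[(delta, k)]
                sens.append(cell.sensitivity)
                spec.append(cell.specificity)
            data[f"sens_delta={delta}"] = sens
            data[f"spec_delta={delta}"] = spec
        return pd.DataFrame(data)


def simulate_outcomes(fit: ModelFit, seed) -> np.ndarray:
    """Draw y*_i ~ Bernoulli(p_i) at the fitted risks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(1, fit.fitted_risks).astype(float)


def run_simulation_study(cohort: CohortTable, fit: ModelFit, plan: SimulationPlan,
                         design: DesignMatrix | None = None,
                         outcomes: np.ndarray | None = None) -> DiagnosticGrid:
    """Run the full parametric-bootstrap diagnostic study.

    ``fit`` must be the original-data fit on ``cohort``. Per-replicate seeds
    are spawned from the plan seed by counter, so extending S re-uses earlier
    replicates' streams unchanged.
    """
    if design is None:
        design = encode_design(cohort, coding=fit.coding)
    if outcomes is None:
        outcomes = cohort.df["outcome"].to_numpy(float)

    original = standardized_risks(fit, design, outcomes)
    truth = {d: gold_standard_labels(original, d) for d in plan.delta_grid}
    truth_counts = {d: int(t.sum()) for d, t in truth.items()}

    cells = {(d, k): DiagnosticSummary() for d in plan.delta_grid for k in plan.k_grid}
    n_penalized = 0
    per_rep_rows = [] if plan.record_per_replicate else None

    seeds = np.random.SeedSequence(plan.seed).spawn(plan.S)
    zq = {k: None for k in plan.k_grid}
    for s in range(plan.S):
        rng = np.random.default_rng(seeds[s])
        y_s = simulate_outcomes(fit, rng)
        refit = fit_casemix_model(design, y_s, start=fit.theta)
        if refit.penalized:
            n_penalized += 1
        risks_s = standardized_risks(refit, design, y_s)
        for k in plan.k_grid:
            lb = one_sided_lower_bound(risks_s.R, risks_s.SE, k)
            for d in plan.delta_grid:
                B_s = benchmark_value(risks_s.population_risk, d)
                flagged = lb > B_s
                t = truth[d]
                cell = cells[(d, k)]
                cell.tp += int(np.sum(flagged & t))
                cell.fn += int(np.sum(~flagged & t))
                cell.fp += int(np.sum(flagged & ~t))
                cell.tn += int(np.sum(~flagged & ~t))
                if per_rep_rows is not None:
                    per_rep_rows.append({"replicate": s, "delta": d, "k": k,
                                         "n_flagged": int(flagged.sum()),
                                         "population_risk": risks_s.population_risk})

    per_rep = pd.DataFrame(per_rep_rows) if per_rep_rows is not None else None
    return DiagnosticGrid(cells=cells, truth_counts=truth_counts,
                          n_penalized_refits=n_penalized, S=plan.S, m=fit.m,
                          delta_grid=tuple(plan.delta_grid),
                          k_grid=tuple(plan.k_grid), per_replicate=per_rep)


def export_grid(grid: DiagnosticGrid, path, *, layout: str = "long",
                delimiter: str = ",") -> None:
    """Write the diagnostic grid as delimited text (bit-stable across calls).

    ``layout="table4"`` mirrors the wide k-by-delta sensitivity/specificity
    table; ``layout="long"`` has one row per (delta, k) with all metrics and
    the raw 2x2 counts.
    """
    if layout == "table4":
        df = grid.to_table4_frame()
    elif layout == "long":
        df = grid.to_long_frame()
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df.to_csv(path, sep=delimiter, index=False, na_rep="undefined", float_format="%.10g")
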