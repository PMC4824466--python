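"""Benchmark decision rule and diagnostic summaries.

A hospital is flagged as outlying when the k-level one-sided lower confidence
bound of its standardized risk strictly exceeds the benchmark
B = (1 + delta) x observed population risk. delta is the clinically chosen
relative excess margin; k is the statistical confidence demanded before
labelling. Gold-standard (truth) labels compare the point estimates R_h from
the original fit against the original benchmark, again strictly: a hospital
exactly at B is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .standardize import StandardizedRiskSet, one_sided_lower_bound

__all__ = [
    "DecisionConfig",
    "DecisionSet",
    "DiagnosticSummary",
    "benchmark_value",
    "classify_hospitals",
    "gold_standard_labels",
    "compute_diagnostics",
]

#: Default evaluation grids: the published margin grid and confidence levels
#: (k printed as percentages 10/30/50/75/90/99) plus the conventional 0.95.
DEFAULT_DELTA_GRID = (0.0, 0.10, 0.15, 0.20)
DEFAULT_K_GRID = (0.10, 0.30, 0.50, 0.75, 0.90, 0.95, 0.99)


@dataclass
class DecisionConfig:
    """One (delta, k) operating point of the decision rule."""

    delta: float = 0.0
    k: float = 0.95

    def __post_init__(self) -> None:
        if self.delta < -1:
            raise ValueError("delta must be >= -1")
        if not 0.0 < self.k < 1.0:
            raise ValueError("k must be in (0, 1)")


@dataclass
class DecisionSet:
    """Classification of every hospital at one (delta, k) operating point."""

    hospital_ids: list[str]
    benchmark: float
    lower_bounds: np.ndarray
    outlying: np.ndarray  # boolean; True = outlying, False = acceptable

    @property
    def labels(self) -> list[str]:
        return ["outlying" if o else "acceptable" for o in self.outlying]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hospital_id": self.hospital_ids,
            "lower_bound": self.lower_bounds,
            "benchmark": self.benchmark,
            "label": self.labels,
        })

    def export(self, path, *, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass
class DiagnosticSummary:
    """Pooled 2x2 classification table and derived diagnostics.

    Metrics whose denominator is empty are ``None`` (a distinguished
    undefined marker), never NaN arithmetic.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def percent_correct(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "percent_correct": self.percent_correct,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def benchmark_value(population_risk: float, delta: float) -> float:
    """The benchmark B = (1 + delta) x observed population risk."""
    return (1.0 + delta) * population_risk


def classify_hospitals(risks: StandardizedRiskSet, config: DecisionConfig) -> DecisionSet:
    """Apply the decision rule to every hospital.

    Outlying iff the k-level lower bound of R_h strictly exceeds
    (1 + delta) x population risk.
    """
    B = benchmark_value(risks.population_risk, config.delta)
    lb = one_sided_lower_bound(risks.R, risks.SE, config.k)
    return DecisionSet(hospital_ids=list(risks.hospital_ids), benchmark=B,
                       lower_bounds=lb, outlying=lb > B)


def gold_standard_labels(risks: StandardizedRiskSet, delta: float) -> np.ndarray:
    """Truth labels from the original fit: excess iff R_h > (1+delta) x pop risk."""
    B = benchmark_value(risks.population_risk, delta)
    return np.asarray(risks.R) > B


def compute_diagnostics(decisions: np.ndarray, truth: np.ndarray) -> DiagnosticSummary:
    """Pool hospital x replicate decisions against fixed per-hospital truth.

    ``decisions`` is boolean with shape (replicates, hospitals) or
    (hospitals,); ``truth`` is boolean per hospital. All pairs enter one 2x2
    table — equivalent to averaging per-replicate rates because truth is
    fixed across replicates.
    """
    decisions = np.atleast_2d(np.asarray(decisions, bool))
    truth = np.asarray(truth, bool)
    if decisions.shape[1] != truth.shape[0]:
        raise ValueError("decisions and truth are misaligned")
    S = decisions.shape[0]
    flags = decisions.sum(axis=0)            # per hospital: replicates flagged
    tp = int(flags[truth].sum())
    fn = int((S - flags[truth]).sum())
    fp = int(flags[~truth].sum())
    tn = int((S - flags[~truth]).sum())
    return DiagnosticSummary(tp=tp, fp=fp, tn=tn, fn=fn)
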