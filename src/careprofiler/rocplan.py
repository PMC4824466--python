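"""Theoretical ROC planning for the benchmark decision rule.

Given last period's standardized risks R_h and standard errors, and a margin
delta, the planner computes — under a normal sampling model
R_hat_h ~ N(R_h, SE_h^2) — the probability each hospital would be flagged at
confidence k, and from those the theoretical sensitivity and specificity
over a k grid, summarized as an ROC curve. Truth per hospital is taken from
the point estimate: excess iff R_h > B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .decision import benchmark_value
from .standardize import StandardizedRiskSet

__all__ = [
    "PlannerInput",
    "RocCurve",
    "flag_probability",
    "theoretical_roc",
    "export_planner",
]

_DEFAULT_K_GRID = tuple(np.round(np.arange(0.01, 1.0, 0.01), 2))


@dataclass
class PlannerInput:
    """Hospital risks/SEs plus the margin delta and the k grid to scan.

    If ``population_risk`` is omitted it defaults to the unweighted mean of
    the supplied R values — a deliberate, documented convention; supply the
    crude observed risk when you have it.
    """

    hospital_ids: list[str]
    R: np.ndarray
    SE: np.ndarray
    delta: float = 0.0
    population_risk: float | None = None
    k_grid: tuple[float, ...] = _DEFAULT_K_GRID

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        self.SE = np.asarray(self.SE, float)
        if (self.SE <= 0).any():
            raise ValueError("all SEs must be positive")
        if ((self.R <= 0) | (self.R >= 1)).any():
            raise ValueError("all risks must be in (0, 1)")

    @property
    def effective_population_risk(self) -> float:
        if self.population_risk is not None:
            return self.population_risk
        return float(self.R.mean())

    @classmethod
    def from_risk_set(cls, risks: StandardizedRiskSet, *, delta: float = 0.0,
                      k_grid: tuple[float, ...] = _DEFAULT_K_GRID) -> "PlannerInput":
        return cls(list(risks.hospital_ids), risks.R, risks.SE, delta=delta,
                   population_risk=risks.population_risk, k_grid=k_grid)


@dataclass
class RocCurve:
    """Theoretical operating characteristics along the k grid."""

    k: np.ndarray
    sensitivity: np.ndarray      # NaN where the excess class is empty
    specificity: np.ndarray      # NaN where the acceptable class is empty
    flag_prob: np.ndarray        # (len(k), n_hospitals)
    hospital_ids: list[str]
    benchmark: float
    truth: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"k": self.k, "sensitivity": self.sensitivity,
                           "specificity": self.specificity})
        for j, hid in enumerate(self.hospital_ids):
            df[f"flag_prob_{hid}"] = self.flag_prob[:, j]
        return df


def flag_probability(R, SE, B: float, k: float):
    """P(flag) under the normal model: Phi((R - B)/SE - z_k).

    The rule flags when the k-level lower bound R_hat - z_k SE exceeds B;
    with R_hat ~ N(R, SE^2) that event has exactly this probability. At
    R = B it equals 1 - k.
    """
    R = np.asarray(R, float)
    SE = np.asarray(SE, float)
    return norm.cdf((R - B) / SE - norm.ppf(k))


def theoretical_roc(inp: PlannerInput) -> RocCurve:
    """Scan the k grid, averaging flag probabilities within each truth class.

    sensitivity(k) = mean flag probability over truly-excess hospitals
    (R_h > B); specificity(k) = mean non-flag probability over acceptable
    hospitals. An empty class yields NaN for its metric at every k.
    """
    B = benchmark_value(inp.effective_population_risk, inp.delta)
    truth = inp.R > B
    ks = np.asarray(inp.k_grid, float)
    fp = np.stack([flag_probability(inp.R, inp.SE, B, k) for k in ks])
    n_exc = int(truth.sum())
    n_acc = int((~truth).sum())
    sens = fp[:, truth].mean(axis=1) if n_exc else np.full(len(ks), np.nan)
    spec = (1.0 - fp[:, ~truth]).mean(axis=1) if n_acc else np.full(len(ks), np.nan)
    return RocCurve(k=ks, sensitivity=sens, specificity=spec, flag_prob=fp,
                    hospital_ids=list(inp.hospital_ids), benchmark=B, truth=truth)


def export_planner(curve: RocCurve, path, *, delimiter: str = ",",
                   plot_path=None, pv_plot_path=None,
                   prevalence: float | None = None) -> None:
    """Write k, sensitivity, specificity and per-hospital flag probabilities.

    Optional matplotlib figures: the ROC curve and, if a prevalence of truly
    outlying hospitals is supplied, PPV/NPV against k.
    """
    curve.to_frame().to_csv(path, sep=delimiter, index=False,
                            na_rep="undefined", float_format="%.10g")
    if plot_path is not None or pv_plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if plot_path is not None:
            fig, ax = plt.subplots()
            ax.plot(1.0 - curve.specificity, curve.sensitivity, marker=".")
            ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            ax.set_title(f"Theoretical ROC (benchmark B={curve.benchmark:.3f})")
            fig.savefig(plot_path)
            plt.close(fig)
        if pv_plot_path is not None:
            pi = prevalence if prevalence is not None else float(curve.truth.mean())
            sens, spec = curve.sensitivity, curve.specificity
            with np.errstate(invalid="ignore", divide="ignore"):
                ppv = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
                npv = spec * (1 - pi) / (spec * (1 - pi) + (1 - sens) * pi)
            fig, ax = plt.subplots()
            ax.plot(curve.k, ppv, label="PPV")
            ax.plot(curve.k, npv, ls="--", label="NPV")
            ax.set_xlabel("k")
            ax.set_ylabel("predictive value")
            ax.legend()
            fig.savefig(pv_plot_path)
            plt.close(fig)
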