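"""Direct standardization of hospital risks and their delta-method variance.

The standardized risk R_h is the mean, over ALL included patients, of the
counterfactual risk p_ih = expit(beta0 + x_i'beta + psi_h): the estimated
proportion of the whole study population that would be dead or ADL-dependent
at 3 months if everyone received hospital h's level of care. Its sampling
variance follows from the delta method applied to the MLE: with gradient

    g_h = (1/n) sum_i p_ih (1 - p_ih) x_i(h),

where x_i(h) is patient i's design row with the hospital columns replaced by
hospital h's pattern, Var(R_h) = g_h' Cov(theta) g_h. The delta method here
conditions on the observed covariate sample (treated as fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .casemix import ModelFit
from .registry import DesignMatrix

__all__ = [
    "StandardizedRiskSet",
    "standardized_risks",
    "delta_method_se",
    "one_sided_lower_bound",
]


@dataclass
class StandardizedRiskSet:
    """Per-hospital standardized risks R_h with SEs and the crude population risk."""

    hospital_ids: list[str]
    R: np.ndarray
    SE: np.ndarray
    population_risk: float
    n: int

    def lower_bounds(self, k: float) -> np.ndarray:
        return one_sided_lower_bound(self.R, self.SE, k)

    def to_frame(self, k: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"hospital_id": self.hospital_ids,
                           "R": self.R, "SE": self.SE})
        if k is not None:
            df[f"lower_bound_k={k}"] = self.lower_bounds(k)
        return df

    def export(self, path, *, k: float | None = None, delimiter: str = ",") -> None:
        """Write hospital_id, R, SE (and optionally the k-level lower bound)."""
        self.to_frame(k).to_csv(path, sep=delimiter, index=False)

    @classmethod
    def from_file(cls, path, *, population_risk: float | None = None,
                  delimiter: str = ",") -> "StandardizedRiskSet":
        df = pd.read_csv(path, sep=delimiter)
        R = df["R"].to_numpy(float)
        pop = population_risk if population_risk is not None else float(R.mean())
        return cls(df["hospital_id"].astype(str).tolist(), R,
                   df["SE"].to_numpy(float), pop, n=len(df))


def _counterfactual_risks(fit: ModelFit, design: DesignMatrix) -> np.ndarray:
    """(m, n) matrix of p_ih over all patients i and hospitals h."""
    k = fit.n_covariate_columns
    eta_cov = design.X[:, :k] @ fit.theta[:k]
    psi = fit.psi_full()
    return expit(eta_cov[None, :] + psi[:, None])


def standardized_risks(fit: ModelFit, design: DesignMatrix,
                       outcomes: np.ndarray) -> StandardizedRiskSet:
    """Compute R_h for every hospital plus delta-method SEs.

    ``outcomes`` supplies the crude observed population risk (mean of y);
    the population risk is deliberately NOT model-based.
    """
    P = _counterfactual_risks(fit, design)
    R = P.mean(axis=1)
    SE = _delta_method_all(fit, design, P)
    pop = float(np.asarray(outcomes, float).mean())
    return StandardizedRiskSet(hospital_ids=list(fit.hospital_levels), R=R,
                               SE=SE, population_risk=pop, n=design.n)


def _delta_method_all(fit: ModelFit, design: DesignMatrix,
                      P: np.ndarray | None = None) -> np.ndarray:
    """Delta-method SEs for every hospital at once.

    The gradient splits into the covariate block (1/n) Xc' w_h and the
    hospital block pattern_h * mean(w_h), with w_h = p_ih (1 - p_ih).
    """
    if P is None:
        P = _counterfactual_risks(fit, design)
    k = fit.n_covariate_columns
    n = design.n
    W = P * (1.0 - P)                       # (m, n)
    Xc = design.X[:, :k]
    G_cov = (W @ Xc) / n                    # (m, k)
    mean_w = W.mean(axis=1)                 # (m,)
    m = fit.m
    G_hosp = np.zeros((m, m - 1))
    for h, hid in enumerate(fit.hospital_levels):
        G_hosp[h] = design.hospital_pattern(hid) * mean_w[h]
    G = np.hstack([G_cov, G_hosp])          # (m, dim theta)
    C = fit.covariance
    # guard: delta method needs a PSD covariance
    eig_min = float(np.linalg.eigvalsh(C).min())
    if eig_min < -1e-8 * max(1.0, float(np.abs(C).max())):
        raise ValueError("covariance matrix is not positive semidefinite")
    var = np.einsum("hj,jk,hk->h", G, C, G)
    return np.sqrt(np.maximum(var, 0.0))


def delta_method_se(fit: ModelFit, design: DesignMatrix, hospital: str) -> float:
    """Delta-method standard error of R_h for one hospital."""
    if hospital not in fit.hospital_levels:
        raise KeyError(f"unknown hospital id: {hospital!r}")
    SE = _delta_method_all(fit, design)
    return float(SE[fit.hospital_levels.index(hospital)])


def one_sided_lower_bound(R, SE, k: float):
    """Lower bound of the k x 100% one-sided normal CI: R - z_k * SE.

    At k = 0.5 this is R itself; the bound decreases as k grows. It may go
    negative for very small hospitals and is not clipped — it is only ever
    compared against the benchmark.
    """
    if not 0.0 < k < 1.0:
        raise ValueError("confidence level k must be in (0, 1)")
    return np.asarray(R, float) - norm.ppf(k) * np.asarray(SE, float)
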