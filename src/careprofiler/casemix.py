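"""Fixed-effects multiple logistic regression for case-mix adjustment.

The model is

    logit(p_i) = beta0 + x_i' beta + sum_{h=2}^{m} I_h psi_h

with one fixed effect psi_h per non-reference hospital and no
hospital-covariate interactions. Fitting is straight Newton/IRLS maximum
likelihood with the covariance taken as the inverse observed Fisher
information at the optimum. When a refit runs into (quasi-)separation — a
realistic event when small hospitals draw zero-event bootstrap resamples —
the fit falls back to Firth's bias-reduced penalized likelihood so every
hospital stays in the analysis with finite estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2, norm

from .registry import DesignMatrix, encode_covariate_row

__all__ = [
    "ModelFit",
    "fit_casemix_model",
    "predict_risk",
    "hospital_or_vs_average",
    "coefficient_table",
]

_MAX_ITER = 100
_LL_RTOL = 1e-10
_SEPARATION_PSI = 10.0


@dataclass
class ModelFit:
    """Fitted model: coefficients, covariance, and per-patient fitted risks."""

    theta: np.ndarray
    covariance: np.ndarray
    fitted_risks: np.ndarray
    converged: bool
    penalized: bool
    loglik: float
    coding: str
    column_labels: list[str]
    hospital_levels: list[str]
    n_covariate_columns: int

    @property
    def m(self) -> int:
        return len(self.hospital_levels)

    def psi_full(self) -> np.ndarray:
        """Hospital effects for all m hospitals on the reference-hospital scale.

        Under reference coding the reference hospital's effect is 0; under
        effects coding the reference level's effect is minus the sum of the
        fitted hospital coefficients.
        """
        k = self.n_covariate_columns
        coefs = self.theta[k:]
        if self.coding == "reference":
            return np.concatenate([[0.0], coefs])
        return np.concatenate([[-float(np.sum(coefs))], coefs])


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = sorted(labels[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {dropped}")


def _newton_mle(X: np.ndarray, y: np.ndarray, start: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    """Newton-Raphson MLE. Returns (theta, XtWX, loglik, converged, separated)."""
    theta = start.copy()
    eta = X @ theta
    ll = _loglik(y, eta)
    separated = False
    converged = False
    A = np.eye(X.shape[1])
    for _ in range(_MAX_ITER):
        p = expit(eta)
        w = p * (1.0 - p)
        A = (X * w[:, None]).T @ X
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < 1e-8 * max(1.0, np.abs(X).max()):
            converged = True
            break
        try:
            c = cho_factor(A)
            step = cho_solve(c, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving if the likelihood would decrease
        new_theta = theta + step
        new_eta = X @ new_theta
        new_ll = _loglik(y, new_eta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_theta = theta + step
            new_eta = X @ new_theta
            new_ll = _loglik(y, new_eta)
            halvings += 1
        theta, eta = new_theta, new_eta
        if np.max(np.abs(theta)) > 80.0 or np.linalg.norm(step) > 1e3:
            separated = True
            ll = new_ll
            break
        ll = new_ll
    p = expit(eta)
    w = p * (1.0 - p)
    A = (X * w[:, None]).T @ X
    return theta, A, ll, converged, separated


def _firth_fit(X: np.ndarray, y: np.ndarray, start: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Firth bias-reduced logistic fit: score adjusted by hat-value leverages."""
    theta = np.zeros_like(start)
    converged = False
    A = np.eye(X.shape[1])
    for _ in range(_MAX_ITER):
        eta = X @ theta
        p = expit(eta)
        w = p * (1.0 - p)
        A = (X * w[:, None]).T @ X
        try:
            c = cho_factor(A)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(X.shape[1])
            c = cho_factor(A)
        # leverages h_i = w_i * x_i' A^{-1} x_i
        M = cho_solve(c, X.T)
        hat = w * np.einsum("ij,ji->i", X, M)
        score = X.T @ (y - p + hat * (0.5 - p))
        step = cho_solve(c, score)
        # dampen huge steps
        nrm = np.linalg.norm(step)
        if nrm > 5.0:
            step *= 5.0 / nrm
        theta = theta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = X @ theta
    ll = _loglik(y, eta)
    p = expit(eta)
    w = p * (1.0 - p)
    A = (X * w[:, None]).T @ X
    return theta, A, ll, converged


def fit_casemix_model(design: DesignMatrix, outcomes: np.ndarray, *,
                      start: np.ndarray | None = None,
                      allow_penalized: bool = True) -> ModelFit:
    """Fit the fixed-effects logistic model by maximum likelihood.

    ``start`` warm-starts Newton iterations (used heavily by the bootstrap
    refits). On separation or nonconvergence the fit is redone with a Firth
    penalty (``penalized`` flag set) unless ``allow_penalized`` is False.
    """
    X = design.X
    y = np.asarray(outcomes, float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcomes length does not match design rows")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcomes must be binary 0/1")
    _check_rank(X, design.column_labels)

    if start is None:
        start = np.zeros(X.shape[1])
        # intercept at the logit of the crude rate speeds convergence
        rate = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        start[0] = np.log(rate / (1 - rate))

    theta, A, ll, converged, separated = _newton_mle(X, y, start)

    k = design.n_covariate_columns
    psi_bad = np.max(np.abs(theta[k:])) > _SEPARATION_PSI if X.shape[1] > k else False
    penalized = False
    if (separated or not converged or psi_bad) and allow_penalized:
        theta, A, ll, converged = _firth_fit(X, y, start)
        penalized = True

    try:
        c = cho_factor(A)
        cov = cho_solve(c, np.eye(A.shape[0]))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    cov = 0.5 * (cov + cov.T)
    fitted = expit(X @ theta)
    return ModelFit(theta=theta, covariance=cov, fitted_risks=fitted,
                    converged=converged, penalized=penalized, loglik=ll,
                    coding=design.coding, column_labels=design.column_labels,
                    hospital_levels=design.hospital_levels,
                    n_covariate_columns=k)


def predict_risk(fit: ModelFit, record: dict, hospital: str) -> float:
    """Counterfactual risk p_ih: the patient's risk under hospital h's care."""
    if hospital not in fit.hospital_levels:
        raise KeyError(f"unknown hospital id: {hospital!r}")
    xc = encode_covariate_row(record)
    beta = fit.theta[: fit.n_covariate_columns]
    h = fit.hospital_levels.index(hospital)
    return float(expit(xc @ beta + fit.psi_full()[h]))


def hospital_or_vs_average(fit: ModelFit) -> pd.Series:
    """Odds ratio of each hospital versus the average over all m hospitals.

    OR_h = exp(psi_h - mean(psi)), the exponentiated effects-coding effect;
    the geometric mean over hospitals is 1 by construction.
    """
    psi = fit.psi_full()
    ors = np.exp(psi - psi.mean())
    return pd.Series(ors, index=fit.hospital_levels, name="odds_ratio_vs_average")


_FACTORS = {
    "sex": ["sex=male"],
    "consciousness": ["consciousness=drowsy", "consciousness=unconscious"],
    "subtype": ["subtype=ischemic", "subtype=unspecified"],
    "smoking": ["smoking=yes", "smoking=unknown"],
    "atrial_fibrillation": ["atrial_fibrillation=yes"],
    "diabetes": ["diabetes=yes"],
}


def coefficient_table(fit: ModelFit, design: DesignMatrix | None = None,
                      outcomes: np.ndarray | None = None) -> pd.DataFrame:
    """Estimates, SEs, odds ratios with 95% Wald CIs and p-values.

    Wald CIs use z = 1.96 exactly. When the design and outcomes are supplied,
    multi-level factors additionally get a likelihood-ratio p-value for the
    whole factor (one p-value per factor, as such tables are printed).
    """
    est = fit.theta
    se = np.sqrt(np.diag(fit.covariance))
    z = est / se
    rows = pd.DataFrame({
        "term": fit.column_labels,
        "estimate": est,
        "se": se,
        "or": np.exp(est),
        "ci_low": np.exp(est - 1.96 * se),
        "ci_high": np.exp(est + 1.96 * se),
        "p_wald": 2 * norm.sf(np.abs(z)),
    }).set_index("term")

    if design is not None and outcomes is not None and not fit.penalized:
        lr_p = {}
        labels = design.column_labels
        for factor, terms in _FACTORS.items():
            cols = [labels.index(t) for t in terms if t in labels]
            if not cols:
                continue
            keep = [j for j in range(design.X.shape[1]) if j not in cols]
            sub = DesignMatrix(design.X[:, keep], [labels[j] for j in keep],
                               design.coding, design.hospital_levels,
                               n_covariate_columns=design.n_covariate_columns - len(cols))
            reduced = fit_casemix_model(sub, outcomes, allow_penalized=False)
            stat = 2.0 * (fit.loglik - reduced.loglik)
            lr_p[factor] = float(chi2.sf(max(stat, 0.0), df=len(cols)))
        rows["p_lr_factor"] = pd.Series(
            {t: lr_p[f] for f, ts in _FACTORS.items() if f in lr_p for t in ts})
    return rows


def export_coefficient_table(table: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    table.to_csv(path, sep=delimiter)
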