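"""Registry data model: delimited-text I/O, inclusion filtering, design encoding.

A cohort is one row per patient: baseline covariates used for case-mix
adjustment (age, sex, level of consciousness at admission, stroke subtype,
smoking status, atrial fibrillation, diabetes), the treating hospital, and a
binary outcome (dead or ADL-dependent at 3 months after stroke). The outcome
may be missing prior to inclusion filtering (lost to follow-up).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORICAL_LEVELS",
    "COVARIATE_COLUMNS",
    "REQUIRED_COLUMNS",
    "CohortTable",
    "ExclusionReport",
    "DesignMatrix",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_criteria",
    "encode_design",
    "encode_covariate_row",
]

#: Allowed levels per categorical field. Reference level listed first —
#: female / alert / hemorrhagic / non-smoker / no AF / no diabetes, matching
#: the reference cells of the fitted odds-ratio table.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "consciousness": ["alert", "drowsy", "unconscious"],
    "subtype": ["hemorrhagic", "ischemic", "unspecified"],
    "smoking": ["no", "yes", "unknown"],
    "atrial_fibrillation": ["no", "yes"],
    "diabetes": ["no", "yes"],
}

COVARIATE_COLUMNS = [
    "age",
    "sex",
    "consciousness",
    "subtype",
    "smoking",
    "atrial_fibrillation",
    "diabetes",
]

REQUIRED_COLUMNS = ["patient_id", *COVARIATE_COLUMNS, "hospital_id", "outcome"]

#: Strings treated as missing values in the delimited text format.
MISSING_TOKENS = {"", "NA"}

#: Inclusive age eligibility bounds (years).
AGE_BOUNDS = (18.0, 80.0)


@dataclass
class CohortTable:
    """An ordered collection of patient records backed by a DataFrame."""

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def m(self) -> int:
        return self.df["hospital_id"].nunique()

    @property
    def hospital_levels(self) -> list[str]:
        """Distinct hospital ids, sorted lexicographically (first = reference)."""
        return sorted(self.df["hospital_id"].unique())

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("cohort must contain at least one record")


@dataclass
class ExclusionReport:
    """Bookkeeping of the inclusion filtering arithmetic."""

    n_eligible: int
    n_lost_followup: int
    n_missing_covariates: int

    @property
    def n_included(self) -> int:
        return self.n_eligible - self.n_lost_followup - self.n_missing_covariates

    def to_dict(self) -> dict[str, int]:
        return {
            "n_eligible": self.n_eligible,
            "n_lost_followup": self.n_lost_followup,
            "n_missing_covariates": self.n_missing_covariates,
            "n_included": self.n_included,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.to_dict().items())


@dataclass
class DesignMatrix:
    """Numeric design matrix with named columns and a hospital-coding scheme.

    ``coding`` is ``"reference"`` (indicator columns for hospitals 2..m, the
    reference hospital all zero) or ``"effects"`` (sum-to-zero coding: the
    reference hospital is -1 in every hospital column, so exponentiated
    hospital effects compare each hospital to the average over all hospitals).
    """

    X: np.ndarray
    column_labels: list[str]
    coding: str
    hospital_levels: list[str]
    n_covariate_columns: int = field(default=0)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return len(self.hospital_levels)

    def hospital_pattern(self, hospital_id: str) -> np.ndarray:
        """The hospital-column pattern a patient treated at ``hospital_id`` has."""
        levels = self.hospital_levels
        if hospital_id not in levels:
            raise KeyError(f"unknown hospital id: {hospital_id!r}")
        ncol = self.m - 1
        pat = np.zeros(ncol)
        idx = levels.index(hospital_id)
        if idx == 0:
            if self.coding == "effects":
                pat[:] = -1.0
        else:
            pat[idx - 1] = 1.0
        return pat


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).str.strip().isin(MISSING_TOKENS)


def read_cohort(path, *, delimiter: str = ",") -> CohortTable:
    """Read a delimited-text cohort file (header row required, UTF-8).

    Empty strings and ``NA`` are missing. Categorical fields are validated
    against their allowed levels; offending rows are reported by number.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {', '.join(missing_cols)}")
    df = df[REQUIRED_COLUMNS].copy()

    # age: numeric or missing
    age_missing = _is_missing(df["age"])
    age = pd.to_numeric(df["age"].where(~age_missing), errors="coerce")
    bad_age = (~age_missing) & age.isna()
    if bad_age.any():
        rows = df.index[bad_age].tolist()[:10]
        raise ValueError(f"unparseable age values at row(s) {rows}")
    df["age"] = age

    for col, levels in CATEGORICAL_LEVELS.items():
        miss = _is_missing(df[col])
        bad = (~miss) & ~df[col].isin(levels)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            vals = sorted(df.loc[bad, col].unique())
            raise ValueError(
                f"unknown level(s) {vals} for {col!r} at row(s) {rows}"
            )
        df.loc[miss, col] = pd.NA

    out_miss = _is_missing(df["outcome"])
    out = pd.to_numeric(df["outcome"].where(~out_miss), errors="coerce")
    bad_out = (~out_miss) & ~out.isin([0, 1])
    if bad_out.any():
        rows = df.index[bad_out].tolist()[:10]
        raise ValueError(f"outcome must be 0/1/missing; bad row(s) {rows}")
    df["outcome"] = out

    hosp_miss = _is_missing(df["hospital_id"])
    if hosp_miss.any():
        rows = df.index[hosp_miss].tolist()[:10]
        raise ValueError(f"missing hospital_id at row(s) {rows}")

    return CohortTable(df)


def write_cohort(cohort: CohortTable, path, *, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text; round-trips through read_cohort."""
    df = cohort.df.copy()
    # Serialize so numeric fields re-parse identically: age repr-stable,
    # outcome as bare integers, missing as empty string.
    df["age"] = df["age"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["outcome"] = df["outcome"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df = df.fillna("")
    df.to_csv(path, sep=delimiter, index=False)


def apply_inclusion_criteria(cohort: CohortTable) -> tuple[CohortTable, ExclusionReport]:
    """Apply the study's inclusion filtering and report the arithmetic.

    Order: (1) age restricted to the inclusive eligibility window 18-80, which
    defines ``n_eligible``; (2) records with missing outcome removed (lost to
    follow-up); (3) records with any missing covariate other than smoking
    removed; missing smoking status is recoded to the ``"unknown"`` level
    rather than excluded.
    """
    df = cohort.df
    lo, hi = AGE_BOUNDS
    eligible = df[df["age"].notna() & (df["age"] >= lo) & (df["age"] <= hi)].copy()
    n_eligible = len(eligible)

    lost = eligible["outcome"].isna()
    n_lost = int(lost.sum())
    followed = eligible[~lost].copy()

    followed.loc[followed["smoking"].isna(), "smoking"] = "unknown"
    other_covs = [c for c in COVARIATE_COLUMNS if c != "smoking"]
    miss_cov = followed[other_covs].isna().any(axis=1)
    n_miss = int(miss_cov.sum())
    included = followed[~miss_cov].copy()

    if len(included) == 0:
        raise ValueError("no included patients after inclusion filtering")

    included["outcome"] = included["outcome"].astype(int)
    report = ExclusionReport(n_eligible, n_lost, n_miss)
    return CohortTable(included.reset_index(drop=True)), report


def _covariate_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n), df["age"].to_numpy(float)]
    labels = ["intercept", "age"]
    for col, levels in CATEGORICAL_LEVELS.items():
        for level in levels[1:]:
            cols.append((df[col] == level).to_numpy(float))
            labels.append(f"{col}={level}")
    return np.column_stack(cols), labels


def encode_design(cohort: CohortTable, coding: str = "reference") -> DesignMatrix:
    """Encode an included cohort as a numeric design matrix.

    Column order is deterministic: intercept, age, the categorical dummies in
    declaration order (reference levels dropped), then one hospital column per
    non-reference hospital. The reference hospital is the lexicographically
    smallest id.
    """
    if coding not in ("reference", "effects"):
        raise ValueError(f"unknown coding {coding!r}")
    df = cohort.df
    if df[COVARIATE_COLUMNS].isna().any().any() or df["outcome"].isna().any():
        raise ValueError("cohort contains missing values; apply inclusion criteria first")
    levels = cohort.hospital_levels
    m = len(levels)
    if m < 2:
        raise ValueError("at least two hospitals are required for a hospital contrast")

    Xc, labels = _covariate_design(df)
    n_cov = len(labels)

    hosp = df["hospital_id"].to_numpy()
    H = np.zeros((len(df), m - 1))
    for j, level in enumerate(levels[1:], start=1):
        H[:, j - 1] = hosp == level
    if coding == "effects":
        H[hosp == levels[0], :] = -1.0
    labels = labels + [f"hospital={lv}" for lv in levels[1:]]
    X = np.hstack([Xc, H])
    return DesignMatrix(X, labels, coding, levels, n_covariate_columns=n_cov)


def encode_covariate_row(record: dict) -> np.ndarray:
    """Encode a single patient's covariates (intercept..diabetes dummies)."""
    row = [1.0, float(record["age"])]
    for col, levels in CATEGORICAL_LEVELS.items():
        val = record[col]
        if val not in levels:
            raise ValueError(f"unknown level {val!r} for {col!r}")
        for level in levels[1:]:
            row.append(1.0 if val == level else 0.0)
    return np.array(row)
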