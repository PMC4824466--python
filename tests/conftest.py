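import numpy as np
import pandas as pd
import pytest

import careprofiler as cp
from careprofiler.registry import CohortTable


def make_cohort(rows: list[dict]) -> CohortTable:
    """Build a cohort from dicts, filling unspecified fields with defaults."""
    defaults = {"age": 70.0, "sex": "female", "consciousness": "alert",
                "subtype": "hemorrhagic", "smoking": "no",
                "atrial_fibrillation": "no", "diabetes": "no",
                "hospital_id": "A", "outcome": 0}
    recs = []
    for i, row in enumerate(rows):
        rec = {"patient_id": f"p{i:04d}", **defaults, **row}
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["outcome"] = df["outcome"].astype(object).where(pd.notna(df["outcome"]), pd.NA)
    return CohortTable(df)


def binary_cohort(events_by_hospital: dict[str, tuple[int, int]]) -> CohortTable:
    """Cohort with identical covariates: {hospital: (events, total)}."""
    rows = []
    for hid, (events, total) in events_by_hospital.items():
        rows += [{"hospital_id": hid, "outcome": 1}] * events
        rows += [{"hospital_id": hid, "outcome": 0}] * (total - events)
    return make_cohort(rows)


@pytest.fixture(scope="session")
def small_registry():
    """A 5-hospital, ~n=1000 synthetic registry with its fit and design."""
    cfg = cp.default_config_riksstroke()
    cfg.m = 5
    cfg.size_median = 200.0
    cfg.size_log_sd = 0.25
    cfg.size_clip = (100, 400)
    cohort, truth = cp.generate_cohort(cfg, seed=42)
    included, _ = cp.apply_inclusion_criteria(cohort)
    design = cp.encode_design(included, coding="reference")
    y = included.df["outcome"].to_numpy(float)
    fit = cp.fit_casemix_model(design, y)
    return {"config": cfg, "cohort": included, "truth": truth,
            "design": design, "y": y, "fit": fit}


@pytest.fixture(scope="session")
def small_risks(small_registry):
    return cp.standardized_risks(small_registry["fit"], small_registry["design"],
                                 small_registry["y"])
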