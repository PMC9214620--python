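import numpy as np
import pandas as pd
import pytest

from medwas import (SimulationConfig, default_annotations, default_code_lists,
                    generate_cohort, load_code_lists)


@pytest.fixture(scope="session")
def code_lists():
    return load_code_lists(default_code_lists())


@pytest.fixture(scope="session")
def annotations20():
    """All named (non-filler) ingredients of the default formulary."""
    return default_annotations(31)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 3000-delivery null cohort with moderate exposure prevalence."""
    cfg = SimulationConfig(n_deliveries=3000, n_medications=12,
                           exposure_prevalence=0.04, seed=42)
    return generate_cohort(cfg)


def toy_deliveries(dates, ages=None, patients=None):
    """Hand-built delivery table for boundary tests."""
    n = len(dates)
    return pd.DataFrame({
        "patient_id": patients or [f"p{i}" for i in range(n)],
        "delivery_id": [f"d{i}" for i in range(n)],
        "delivery_date": dates,
        "maternal_age": ages or [30.0] * n,
    })


def diag(patient, code, date, system="ICD-10"):
    return {"patient_id": patient, "code_system": system, "code": code, "date": date}


def diag_frame(rows):
    if not rows:
        return pd.DataFrame(columns=["patient_id", "code_system", "code", "date"])
    return pd.DataFrame(rows)


def two_by_two_outcome_design(n11, n10, n01, n00, rng=None):
    """Outcome vector and exposure column realising a 2x2 table
    (exposed MB, exposed non-MB, unexposed MB, unexposed non-MB)."""
    y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
    x = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    return y, x
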