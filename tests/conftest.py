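import numpy as np
import pandas as pd
import pytest

from midpass import CohortTable, build_pairs, generate_cohort
from midpass.simulate import study_regime_config


def make_cohort_df(rows):
    """Build a minimal cohort frame, filling unspecified fields with NA."""
    base = {
        "patient_id": None, "timepoint": None,
        "nrs": np.nan, "prwhe_pain": np.nan, "prwhe_function": np.nan,
        "prwhe_total": np.nan, "grc": np.nan, "pass_satisfied": None,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.fixture
def tiny_cohort():
    """Two patients, baseline + two follow-ups, hand-checkable scores."""
    rows = [
        {"patient_id": "a", "timepoint": "baseline", "nrs": 6,
         "prwhe_pain": 30, "prwhe_function": 20, "prwhe_total": 50},
        {"patient_id": "a", "timepoint": "m3", "nrs": 3, "prwhe_pain": 20,
         "prwhe_function": 12, "prwhe_total": 32, "grc": 2, "pass_satisfied": True},
        {"patient_id": "a", "timepoint": "m6", "nrs": 2, "prwhe_pain": 12,
         "prwhe_function": 8, "prwhe_total": 20, "grc": 1, "pass_satisfied": True},
        {"patient_id": "b", "timepoint": "baseline", "nrs": 8,
         "prwhe_pain": 40, "prwhe_function": 35, "prwhe_total": 75},
        {"patient_id": "b", "timepoint": "m3", "nrs": 8, "prwhe_pain": 39,
         "prwhe_function": 34, "prwhe_total": 73, "grc": 3, "pass_satisfied": False},
        {"patient_id": "b", "timepoint": "m6", "nrs": 7, "prwhe_pain": 38,
         "prwhe_function": 35, "prwhe_total": 73, "grc": 3, "pass_satisfied": False},
    ]
    return CohortTable(make_cohort_df(rows))


@pytest.fixture(scope="session")
def regime_cohort():
    """The bundled study-regime cohort: 50 patients, 250 anchor-outcome pairs."""
    return generate_cohort(study_regime_config(seed=0))


@pytest.fixture(scope="session")
def nrs_pairs(regime_cohort):
    return build_pairs(regime_cohort, "nrs")
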