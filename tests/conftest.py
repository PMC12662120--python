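import numpy as np
import pandas as pd
import pytest

from vhd_aging import clocks, synthetic_cohort as sc


@pytest.fixture(scope="session")
def reference_population():
    """Mid-sized survey-style reference for clock training (ages 30-75)."""
    return sc.simulate_reference_population(
        sc.SimulationConfig(n_participants=6000, seed=301, age_range=(30.0, 75.0))
    )


@pytest.fixture(scope="session")
def kdm_params(reference_population):
    return {
        sex: clocks.fit_kdm_parameters(reference_population, sex_stratum=sex)
        for sex in ("male", "female")
    }


@pytest.fixture(scope="session")
def cohort_and_events():
    """Default-condition synthetic cohort, small enough for unit tests."""
    return sc.simulate_cohort(sc.SimulationConfig(n_participants=12_000, seed=77))


@pytest.fixture(scope="session")
def scored_cohort(cohort_and_events, kdm_params):
    cohort, _ = cohort_and_events
    return clocks.score_cohort(cohort, kdm_params=kdm_params)


@pytest.fixture(scope="session")
def as_analysis(scored_cohort, cohort_and_events):
    """Scored cohort merged with the aortic-stenosis outcome records."""
    _, events = cohort_and_events
    d = sc.event_table_for_outcome(scored_cohort, events, "AS")
    d["event"] = (d["status"] == 1).astype(int)
    return d


def simple_panel(**overrides):
    """One physiologically plausible biomarker panel row."""
    row = {
        "albumin": 45.0,
        "alkaline_phosphatase": 70.0,
        "blood_urea_nitrogen": 5.2,
        "creatinine": 72.0,
        "c_reactive_protein": 0.15,
        "hba1c": 5.4,
        "total_cholesterol": 5.6,
        "fev1": 3.1,
        "systolic_bp": 135.0,
        "glucose": 5.0,
        "mean_cell_volume": 90.0,
        "red_cell_distribution_width": 13.4,
        "white_blood_cell_count": 6.8,
        "lymphocyte_percent": 30.0,
        "chronological_age": 56.0,
        "sex": "female",
    }
    row.update(overrides)
    return pd.DataFrame([row])
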