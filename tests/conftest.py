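import numpy as np
import pandas as pd
import pytest

from deepsofa import (
    SimConfig,
    filter_encounters,
    preprocess_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """120 simulated encounters, filtered — shared read-only test bed."""
    return filter_encounters(simulate_cohort(SimConfig(n_encounters=120, seed=42)))


@pytest.fixture(scope="session")
def small_grids(small_cohort):
    grids, _ = preprocess_cohort(small_cohort)
    return grids


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return small_cohort.labels()


def toy_encounter_row(**overrides):
    row = {
        "encounter_id": "E1",
        "patient_id": "P1",
        "age_years": 50.0,
        "icu_los_hours": 48.0,
        "hosp_discharge_offset_hours": 60.0,
        "died_in_hospital": False,
        "hospice_discharge": False,
        "days_discharge_to_death": np.nan,
        "icu_type": "Medical",
    }
    row.update(overrides)
    return row


def toy_events(rows):
    """rows: list of (encounter_id, variable, offset_hours, value)."""
    return pd.DataFrame(
        rows, columns=["encounter_id", "variable", "offset_hours", "value"]
    )
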