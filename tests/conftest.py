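import numpy as np
import pandas as pd
import pytest

from metdiv.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale 20-patient cohort config used across tests."""
    return CohortConfig(n_patients=20, count_scale=0.002, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_cells(class_counts: dict, section_id: str = "S1", site: str = "omentum",
               patient_id: str = "P1", rng=None) -> pd.DataFrame:
    """Build a cell table with given per-class counts and random coordinates."""
    rng = rng or np.random.default_rng(0)
    classes = np.repeat(list(class_counts), list(class_counts.values()))
    n = len(classes)
    return pd.DataFrame({
        "patient_id": patient_id, "section_id": section_id, "site": site,
        "x": rng.uniform(0, 1000, n), "y": rng.uniform(0, 1000, n),
        "cell_class": classes,
    })
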