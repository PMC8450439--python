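import numpy as np
import pandas as pd
import pytest

from sepsiskit.features import build_feature_matrix
from sepsiskit.labeling import label_cohort
from sepsiskit.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-case / 12-control cohort shared across module tests."""
    cfg = SimulationConfig(n_cases=12, n_controls=12, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    c = small_cohort
    return label_cohort(c.vitals, c.events, c.labs, seed=11)


@pytest.fixture(scope="session")
def small_fm(small_cohort, small_labels):
    return build_feature_matrix(small_labels.labels, small_cohort.vitals)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_labs(patient_id: str, rows: list[tuple[float, str, float]]) -> pd.DataFrame:
    """Lab table from (hour, analyte, value) triples anchored at a fixed epoch."""
    base = pd.Timestamp("2024-01-01 00:00:00", tz="UTC")
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "timestamp": [base + pd.Timedelta(hours=h) for h, _, _ in rows],
            "analyte": [a for _, a, _ in rows],
            "value": [v for _, _, v in rows],
        }
    )


def make_events(patient_id: str, rows: list[tuple[str, float]]) -> pd.DataFrame:
    base = pd.Timestamp("2024-01-01 00:00:00", tz="UTC")
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "event_type": [e for e, _ in rows],
            "timestamp": [base + pd.Timedelta(hours=h) for _, h in rows],
        }
    )


EMPTY_VITALS = pd.DataFrame(
    columns=["patient_id", "timestamp", "hr", "rr", "spo2", "sbp", "dbp", "map"]
)
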