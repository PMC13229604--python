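import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests."""
    from sleepdex.simulate import SimulationConfig, simulate_cohort
    return simulate_cohort(SimulationConfig(n_participants=800, seed=42))


@pytest.fixture()
def toy_events():
    """A hand-built ICD event table with known dedup/window behavior."""
    return pd.DataFrame({
        "participant_id": ["A", "A", "A", "B", "B", "C"],
        "icd_version": [10, 10, 10, 9, 7, 10],
        "code": ["F32.9", "F32.9", "F32.9", "311", "999", "F41.1"],
        "date": ["2020-01-01", "2020-01-01", "2021-06-01",
                 "2020-03-15", "2020-03-15", "2030-01-01"],
    })


@pytest.fixture()
def reference_dates():
    return pd.Series(pd.to_datetime(["2019-05-01", "2019-05-01", "2019-05-01"]),
                     index=pd.Index(["A", "B", "C"], name="participant_id"))
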