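import numpy as np
import pytest

from persisterdyn import (
    DEFAULT_READOUT,
    NoiseModel,
    TreatmentSchedule,
    generate_dataset,
    paperlike_scenarios,
    standard_tmz_schedule,
)


@pytest.fixture(scope="session")
def tmz_schedule() -> TreatmentSchedule:
    """Standard course: TMZ every 3 days, 3-day windows, doses at days 0..15."""
    return standard_tmz_schedule()


@pytest.fixture(scope="session")
def no_drug() -> TreatmentSchedule:
    return TreatmentSchedule()


@pytest.fixture(scope="session")
def scenarios() -> dict:
    return paperlike_scenarios()


@pytest.fixture(scope="session")
def obs_days() -> np.ndarray:
    return np.array([0.0, 4.0, 9.0, 12.0, 16.0])


@pytest.fixture(scope="session")
def noisefree() -> NoiseModel:
    return NoiseModel(count_cv=0.0, mgmt_sd_log2=0.0, n_replicates=1, detection_floor=0.0)


@pytest.fixture(scope="session")
def adaptive_dataset(scenarios):
    """One seeded noisy dataset generated from the adaptive ground truth."""
    ds, truth = generate_dataset(scenarios["full_course"], NoiseModel(), seed=0)
    return ds, truth


@pytest.fixture(scope="session")
def clonal_dataset(scenarios):
    ds, truth = generate_dataset(scenarios["full_course_clonal"], NoiseModel(), seed=0)
    return ds, truth
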