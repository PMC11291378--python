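import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def b_grid():
    """Primary 5-point acquisition grid (s/mm^2)."""
    return np.array([0.0, 30.0, 80.0, 150.0, 500.0])


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by feature/pipeline tests."""
    from dwisurv.synthetic import CohortConfig, simulate_cohort

    cfg = CohortConfig(
        n_patients=10,
        n_sequence2=2,
        grid_shape=(14, 14, 8),
        n_patients_with_missing=1,
    )
    return simulate_cohort(config=cfg, seed=42)
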