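import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A small simulated cohort with a couple of batches, no effects."""
    from t1dglyco.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_families=40, n_batches=3, seed=7))


@pytest.fixture
def percent_table(small_cohort):
    from t1dglyco.preprocess import normalize_total_area

    return normalize_total_area(small_cohort.peak_table)
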