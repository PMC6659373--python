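import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sleepmr import simdata  # noqa: E402


@pytest.fixture(scope="session")
def small_params():
    """A small but structurally complete cohort parameterisation."""
    return simdata.default_sim_params(n=4000, seed=11, k=12, panel_seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simdata.simulate_cohort(small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(2718)
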