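import numpy as np
import pytest

from dnmbc.cohort import default_scenario, generate_cohort, recovery_scenario


@pytest.fixture(scope="session")
def default_specs():
    return default_scenario()


@pytest.fixture(scope="session")
def recovery_specs():
    return recovery_scenario()


@pytest.fixture(scope="session")
def small_cohort(default_specs):
    """A modest default-scenario cohort for unit-level checks."""
    scheme, hazard, assign = default_specs
    return generate_cohort(scheme, hazard, assign, 1200, seed=7)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_specs):
    scheme, hazard, assign = recovery_specs
    return generate_cohort(scheme, hazard, assign, 3000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
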