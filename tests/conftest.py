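import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from glycosim import (  # noqa: E402
    PatientTFParams,
    SimulationConfig,
    printed_continuous_tf,
    printed_state_space,
    tf_to_state_space,
)


@pytest.fixture(scope="session")
def nominal_params() -> PatientTFParams:
    return PatientTFParams()


@pytest.fixture(scope="session")
def printed_tf():
    return printed_continuous_tf()


@pytest.fixture(scope="session")
def printed_ss():
    return printed_state_space()


@pytest.fixture(scope="session")
def sim_plant(printed_tf):
    """Default continuous simulation plant (canonical realization)."""
    return tf_to_state_space(printed_tf)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
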