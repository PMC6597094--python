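import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fcatools import simulated_nine_centers, toy_two_clinics


@pytest.fixture(scope="session")
def simulated():
    """Nine-center / three-clinic worked example (scenario, impedance specs)."""
    return simulated_nine_centers()


@pytest.fixture(scope="session")
def toy():
    """Three-center / two-clinic worked example."""
    return toy_two_clinics()


@pytest.fixture
def rng():
    return np.random.default_rng(20190627)
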