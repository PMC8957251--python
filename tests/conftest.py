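import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbpksim import default_body, make_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def body():
    return default_body()


@pytest.fixture(scope="session")
def amoxicillin():
    return make_scenario("amoxicillin")


@pytest.fixture(scope="session")
def cannabinol():
    return make_scenario("cannabinol")


@pytest.fixture
def grid_600():
    return np.linspace(0.0, 600.0, 241)
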