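import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from surgevents import build_toy_profile

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_xi():
    return build_toy_profile("XI")


@pytest.fixture(scope="session")
def toy_si():
    return build_toy_profile("SI")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230630)
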