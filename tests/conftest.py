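import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160608)


@pytest.fixture(scope="session")
def free_space_fixture():
    from magshield import build_fixture
    return build_fixture("free_space")


@pytest.fixture(scope="session")
def solar_min_spectrum():
    from magshield import synthetic_spectrum
    return synthetic_spectrum("solar_min")
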