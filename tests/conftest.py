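import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vamrstat.protocol import AssayProtocol, build_schedule

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_protocol():
    return AssayProtocol()


@pytest.fixture(scope="session")
def schedule(default_protocol):
    return build_schedule(default_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
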