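import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alchemti import build_schedule

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule19():
    """The 19-window λ grid from 0.05 to 0.95 with 0.05/0.075 weights."""
    return build_schedule(19, 0.05, 0.95)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
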