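import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from corrlaw.observer import ObserverParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20161026)


@pytest.fixture
def basic_observer():
    """Observer calibrated to the basic-condition parameters (b=0.90, k=0.21)."""
    return ObserverParams.from_weber(0.90, 0.21)
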