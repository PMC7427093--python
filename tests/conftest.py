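import pytest
from hypothesis import HealthCheck, settings

from ddstate.hydro import Conditions

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def cond():
    """Default conditions: 303.15 K, pure-water viscosity."""
    return Conditions()


@pytest.fixture
def cond600():
    """Default conditions plus a 600 MHz spectrometer."""
    return Conditions(field_MHz=600.0)
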