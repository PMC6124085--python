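import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_events():
    """The canonical four-event toy log: A groomed B twice on day 1, once on
    day 2, and groomed C once on day 2."""
    from groomnet.io_eventlog import ContactEvent

    return [
        ContactEvent("A", "B", 1),
        ContactEvent("A", "B", 1),
        ContactEvent("A", "B", 2),
        ContactEvent("A", "C", 2),
    ]
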