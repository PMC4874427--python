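import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wingbeat.signals import FrequencyTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def constant_trace(freq_hz: float, duration_s: float = 10.0, rate: float = 1000.0,
                   valid=None) -> FrequencyTrace:
    n = int(round(duration_s * rate))
    mask = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool)
    return FrequencyTrace(np.full(n, float(freq_hz)), mask, rate)


@pytest.fixture
def make_constant_trace():
    return constant_trace
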