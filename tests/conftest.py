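import numpy as np
import pytest
from hypothesis import HealthCheck, settings

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
    return np.random.default_rng(12345)


@pytest.fixture
def hourly_cos():
    """24 hourly samples of a 2-h alternation (cos(pi t) = ±1 on the grid)."""
    from caprhythm import TimeSeries

    t = np.arange(24.0)
    return TimeSeries(t, np.cos(np.pi * t), time_unit="hour")


@pytest.fixture
def monthly_cos12():
    """Noise-free 12-month cosine on the 36-month axis (peak month 11)."""
    from caprhythm import TimeSeries

    m = np.arange(1.0, 37.0)
    return TimeSeries(
        m, 29 + 17 * np.cos(2 * np.pi * (m - 11) / 12), time_unit="month"
    )
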