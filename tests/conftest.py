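import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def linear_series():
    """Noiseless monophasic series declining at 3.37 %/h on a 3-h grid."""
    from woundkin import ClosureSeries

    t = np.arange(0.0, 19.0, 3.0)
    return ClosureSeries(
        condition="BM", replicate="r1", times=t, gap_pct=100.0 - 3.37 * t
    )


@pytest.fixture
def hinge_series():
    """Noiseless biphasic series: 4 %/h until 9 h, then 10 %/h."""
    from woundkin import ClosureSeries

    t = np.arange(0.0, 15.1, 3.0)
    y = np.where(t <= 9.0, 100.0 - 4.0 * t, 100.0 - 4.0 * 9.0 - 10.0 * (t - 9.0))
    return ClosureSeries(condition="CM", replicate="r1", times=t, gap_pct=y)
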