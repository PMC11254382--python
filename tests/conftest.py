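import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_study_kwargs():
    """Timing for a compact study recording: 5-min baseline, ~11 min response."""
    return dict(duration_s=1000.0, t_inj1_end=310.0, t_inj2_end=340.0)
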