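import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """A short deterministic 4-position recording with one scalar channel."""
    from har2dcnn import default_profiles, default_segment_plan, simulate_recording

    profiles = default_profiles(4, 3)
    plan = default_segment_plan(profiles, 1200, base_segment=40)
    return simulate_recording(profiles, 4, plan, scalar_channels=1, seed=7)
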