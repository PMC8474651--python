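import numpy as np
import pytest

from fluoinfo import behavior as bhv
from fluoinfo import experiments as ex


@pytest.fixture(scope="session")
def behavior_pool():
    """Small shared pool of synthetic sessions for pipeline tests."""
    return ex.make_behavior_pool(n_sessions=4, session_minutes=8.0, seed=101)


@pytest.fixture(scope="session")
def ten_min_trace(behavior_pool):
    return ex._draw_session(behavior_pool, 10.0, np.random.default_rng(7))


def make_ramp_trace(
    speed_cm_s: float,
    duration: float,
    sample_rate: float = 50.0,
    track_length: float = 3.0,
):
    """Deterministic constant-speed laps with instantaneous teleports."""
    n = int(round(duration * sample_rate))
    dist = speed_cm_s / 100.0 * np.arange(n) / sample_rate
    pos = np.mod(dist, track_length)
    return bhv.BehaviorTrace(np.arange(n) / sample_rate, pos, sample_rate, track_length)


@pytest.fixture
def ramp_trace():
    return make_ramp_trace
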