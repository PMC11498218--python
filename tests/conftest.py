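import numpy as np
import pytest

from postvigor import ModelParams, UserTrace, compute_latencies


def trace_from_latencies(latencies, likes, user_id="u"):
    """Build a UserTrace directly from defined latencies (days) and likes;
    the first latency is implicitly undefined."""
    lat = np.asarray(latencies, dtype=float)
    likes = np.asarray(likes, dtype=np.int64)
    assert lat.size + 1 == likes.size
    secs = np.round(np.concatenate([[0.0], np.cumsum(lat)]) * 86_400.0).astype("int64")
    ts = np.datetime64("2020-01-01T00:00:00", "s") + secs.astype("timedelta64[s]")
    return compute_latencies(UserTrace(user_id=user_id, timestamps=ts, likes=likes))


@pytest.fixture
def make_trace():
    return trace_from_latencies


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture
def default_params():
    return ModelParams(alpha=0.002, cost=0.5, rho0=2.0)
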