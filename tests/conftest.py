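import numpy as np
import pytest

from mftfcca import (
    TimeSeriesSet,
    make_bidirectional_var41,
    make_unidirectional_xy,
    make_unidirectional_yx,
    simulate_var,
)
from mftfcca.preprocessing import decimate


@pytest.fixture(scope="session")
def uni_xy_ts() -> TimeSeriesSet:
    """X-drives-Y VAR(4) realization with Y down-sampled to 40 Hz."""
    ts = simulate_var(make_unidirectional_xy(), n_trials=20, duration=10.0, seed=101)
    return decimate(ts, "y", 5)


@pytest.fixture(scope="session")
def uni_yx_ts() -> TimeSeriesSet:
    """Y-drives-X VAR(4) realization with X down-sampled to 40 Hz."""
    ts = simulate_var(make_unidirectional_yx(), n_trials=20, duration=10.0, seed=102)
    return decimate(ts, "x", 5)


@pytest.fixture(scope="session")
def var41_ts() -> TimeSeriesSet:
    """Bidirectional VAR(41) realization with Y down-sampled to 40 Hz."""
    ts = simulate_var(make_bidirectional_var41(), n_trials=20, duration=10.0, seed=103)
    return decimate(ts, "y", 5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def white_mf_ts(rng) -> TimeSeriesSet:
    """Independent white-noise channels at 200 / 40 Hz (null system)."""
    trials = [
        {"x": rng.standard_normal(2000), "y": rng.standard_normal(400)}
        for _ in range(8)
    ]
    return TimeSeriesSet(trials, {"x": 200.0, "y": 40.0})
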