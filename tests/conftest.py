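import numpy as np
import pytest

from freezekit.freezing import FreezingParams, MovementTrace
from freezekit.protocol import SessionSchedule, build_schedule
from freezekit.startle import StartleParams


@pytest.fixture(scope="session")
def fparams() -> FreezingParams:
    return FreezingParams()


@pytest.fixture(scope="session")
def sparams() -> StartleParams:
    return StartleParams()


@pytest.fixture(scope="session")
def recall_schedule() -> SessionSchedule:
    """Standard six-tone-block recall session in the training context."""
    return build_schedule("us_only_short", "recall")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_trace(values, fs: float = 30.0) -> MovementTrace:
    return MovementTrace(np.asarray(values, dtype=float), fs)


# ---------------------------------------------------------------------------
# independent oracles shared across test modules

def brute_force_freezing(values, threshold, min_duration, fs) -> np.ndarray:
    """Exhaustive run-length freezing oracle: per-sample scan, no vector ops."""
    n = len(values)
    states = [0] * n
    min_len = int(np.ceil(min_duration * fs - 1e-9))
    i = 0
    while i < n:
        if values[i] < threshold:
            j = i
            while j < n and values[j] < threshold:
                j += 1
            if j - i >= min_len:
                for k in range(i, j):
                    states[k] = 1
            i = j
        else:
            i += 1
    return np.array(states, dtype=np.uint8)


def brute_force_window_pct(states, start_s, end_s, fs) -> float:
    total = 0
    count = 0
    for i, s in enumerate(states):
        t = i / fs
        if start_s <= t < end_s:
            total += int(s)
            count += 1
    return 100.0 * total / count
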