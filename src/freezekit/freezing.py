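"""Freezing-state classification from movement-index traces.

The movement index is a per-frame scalar (arbitrary units) describing how
much the animal moved between consecutive video frames, sampled at the
30 Hz video rate.  A mouse is scored as freezing wherever the index stays
strictly below a threshold (default 40 a.u.) for at least a minimum
duration (default 0.5 s, i.e. 15 samples at 30 Hz).  The binary freezing
trace is then summarized as percent time freezing per fixed-width bin
(default 10 s) or over arbitrary half-open analysis windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MovementTrace",
    "FreezingParams",
    "FreezingTrace",
    "BinnedFreezing",
    "classify_freezing",
    "bin_percent_freezing",
    "window_percent_freezing",
]

SAMPLE_RATE_HZ = 30.0


@dataclass
class MovementTrace:
    """A uniformly sampled movement-index series for one mouse-session."""

    values: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ
    mouse_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("movement trace must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("movement index values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (sample i occurs at i / sample_rate)."""
        return np.arange(self.n_samples) / self.sample_rate

    def copy(self) -> "MovementTrace":
        return MovementTrace(
            self.values.copy(), self.sample_rate, self.mouse_id, self.session_id
        )


@dataclass(frozen=True)
class FreezingParams:
    """Immobility criterion: index < threshold for >= min_duration."""

    threshold: float = 40.0  # arbitrary units
    min_duration: float = 0.5  # seconds

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")

    def min_samples(self, sample_rate: float) -> int:
        """Minimum run length in samples: ceil(min_duration * rate) = 15 at 30 Hz."""
        return max(1, math.ceil(self.min_duration * sample_rate - 1e-9))


@dataclass
class FreezingTrace:
    """Per-sample binary freezing state (1 = freezing)."""

    states: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ
    mouse_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)

    @property
    def n_samples(self) -> int:
        return self.states.size

    def total_freezing_time(self) -> float:
        """Total time scored as freezing, in seconds."""
        return float(self.states.sum()) / self.sample_rate


@dataclass
class BinnedFreezing:
    """Percent time freezing per fixed-width time bin."""

    values: np.ndarray  # percent, [0, 100]
    bin_size: float  # seconds
    sample_rate: float = SAMPLE_RATE_HZ
    #: True if the last bin spans fewer samples than the others; its value
    #: is normalized by its own sample count rather than dropped.
    partial_last_bin: bool = False

    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.values) + 1) * self.bin_size


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def classify_freezing(
    trace: MovementTrace, params: FreezingParams = FreezingParams()
) -> FreezingTrace:
    """Binary freezing state from a movement-index trace.

    A sample is freezing iff it belongs to a maximal run of samples with
    index strictly below ``params.threshold`` whose duration is at least
    ``params.min_duration``.  "Below" is strict: samples exactly at the
    threshold count as movement.  Runs touching the trace boundaries are
    eligible.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot classify an empty trace")
    below = trace.values < params.threshold
    min_len = params.min_samples(trace.sample_rate)
    states = np.zeros(trace.n_samples, dtype=np.uint8)
    starts, lengths = _runs(below)
    for s, n in zip(starts, lengths):
        if n >= min_len:
            states[s : s + n] = 1
    return FreezingTrace(states, trace.sample_rate, trace.mouse_id, trace.session_id)


def bin_percent_freezing(
    freezing: FreezingTrace, bin_size: float = 10.0
) -> BinnedFreezing:
    """Percent time freezing in consecutive half-open bins of ``bin_size`` s.

    A trailing partial bin is normalized by its own sample count and flagged
    through :attr:`BinnedFreezing.partial_last_bin`.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n = freezing.n_samples
    per_bin = bin_size * freezing.sample_rate
    n_bins = math.ceil(n / per_bin - 1e-9)
    values = np.empty(n_bins)
    partial = False
    for k in range(n_bins):
        i0 = int(math.ceil(k * per_bin - 1e-9))
        i1 = min(n, int(math.ceil((k + 1) * per_bin - 1e-9)))
        values[k] = 100.0 * freezing.states[i0:i1].sum() / (i1 - i0)
        if k == n_bins - 1 and (i1 - i0) < int(round(per_bin)):
            partial = True
    return BinnedFreezing(values, bin_size, freezing.sample_rate, partial)


def window_percent_freezing(
    freezing: FreezingTrace, start_s: float, end_s: float
) -> float:
    """Percent time freezing over the half-open window [start_s, end_s)."""
    if end_s <= start_s:
        raise ValueError("window end must exceed start")
    fs = freezing.sample_rate
    i0 = int(math.ceil(start_s * fs - 1e-9))
    i1 = int(math.ceil(end_s * fs - 1e-9))
    if i0 < 0 or i1 > freezing.n_samples:
        raise ValueError(
            f"window [{start_s}, {end_s}) s lies outside the "
            f"{freezing.n_samples / fs:.1f} s trace"
        )
    return 100.0 * float(freezing.states[i0:i1].sum()) / (i1 - i0)
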