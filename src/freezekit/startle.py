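"""Detection and correction of tone-evoked startle movements.

Sharp-onset tone beeps can evoke a short reflexive head movement in an
otherwise immobile mouse.  The video-based movement index picks these up
as motion, so apparent freezing during the CS is slightly underestimated.
The correction detects transient movements initiated within a short window
after a beep onset (default 0.2 s) and shorter than a maximum duration
(default 0.9 s, exclusive), and blanks them from the movement trace —
restricted to the 30-s CS periods — so that each startle is counted as
freezing instead of movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freezing import (
    FreezingParams,
    FreezingTrace,
    MovementTrace,
    _runs,
    classify_freezing,
    window_percent_freezing,
)
from .protocol import SessionSchedule

__all__ = [
    "StartleParams",
    "StartleEvent",
    "detect_startle_events",
    "blank_startles",
    "corrected_cs_freezing",
    "events_to_frame",
]


@dataclass(frozen=True)
class StartleParams:
    """Startle criterion: movement initiated within ``onset_window`` s of a
    beep onset (inclusive at both ends) and lasting less than
    ``max_duration`` s (strict)."""

    onset_window: float = 0.2
    max_duration: float = 0.9

    def __post_init__(self) -> None:
        if self.onset_window <= 0 or self.max_duration <= 0:
            raise ValueError("onset_window and max_duration must be > 0")


@dataclass(frozen=True)
class StartleEvent:
    """One detected beep-locked movement transient."""

    beep_index: int  # index into the flattened beep-onset list
    onset: float  # seconds, first supra-threshold sample
    duration: float  # seconds
    start_sample: int
    n_samples: int
    in_cs_period: bool

    @property
    def end_sample(self) -> int:
        return self.start_sample + self.n_samples


def _in_any_window(t: float, windows: list[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in windows)


def detect_startle_events(
    trace: MovementTrace,
    schedule: SessionSchedule,
    fparams: FreezingParams = FreezingParams(),
    sparams: StartleParams = StartleParams(),
) -> list[StartleEvent]:
    """Find beep-locked movement transients.

    A candidate is a maximal run of samples with index >= the freezing
    threshold.  It is a startle event iff its first sample lies within
    ``[beep_onset, beep_onset + onset_window]`` for some beep — a run
    already ongoing at beep onset was not *initiated* by the beep and is
    excluded — and its duration is strictly shorter than ``max_duration``.
    When several beeps could claim one run the earliest qualifying beep
    does.
    """
    if not schedule.tone_blocks:
        raise ValueError("schedule contains no tone blocks")
    beeps = schedule.beep_onsets()
    cs_windows = schedule.cs_windows()
    fs = trace.sample_rate
    supra = trace.values >= fparams.threshold
    starts, lengths = _runs(supra)
    events: list[StartleEvent] = []
    for s, n in zip(starts, lengths):
        duration = n / fs
        if duration >= sparams.max_duration:
            continue
        onset = s / fs
        # earliest beep whose onset window contains the run onset
        k = np.searchsorted(beeps, onset - sparams.onset_window - 1e-9)
        claimed = None
        for b_idx in range(k, len(beeps)):
            b = beeps[b_idx]
            if b > onset + 1e-9:
                break
            if b - 1e-9 <= onset <= b + sparams.onset_window + 1e-9:
                claimed = b_idx
                break
        if claimed is None:
            continue
        events.append(
            StartleEvent(
                beep_index=int(claimed),
                onset=onset,
                duration=duration,
                start_sample=int(s),
                n_samples=int(n),
                in_cs_period=_in_any_window(onset, cs_windows),
            )
        )
    return events


def blank_startles(
    trace: MovementTrace,
    events: list[StartleEvent],
    schedule: SessionSchedule,
) -> MovementTrace:
    """Zero the samples of each startle event that fall inside a CS period.

    Samples outside the 30-s CS periods are never modified.  Blanked
    samples are written as index 0 so downstream classification is
    independent of the threshold; re-classification then merges the
    sub-threshold runs flanking the blanked span.
    """
    out = trace.copy()
    fs = trace.sample_rate
    for a, b in schedule.cs_windows():
        i0 = int(np.ceil(a * fs - 1e-9))
        i1 = int(np.ceil(b * fs - 1e-9))
        for ev in events:
            lo = max(ev.start_sample, i0)
            hi = min(ev.end_sample, i1)
            if lo < hi:
                out.values[lo:hi] = 0.0
    return out


def corrected_cs_freezing(
    trace: MovementTrace,
    schedule: SessionSchedule,
    fparams: FreezingParams = FreezingParams(),
    sparams: StartleParams = StartleParams(),
) -> tuple[pd.DataFrame, list[StartleEvent]]:
    """Per-CS percent freezing before and after startle correction.

    Returns a frame with one row per tone block (``cs_index`` starting at
    1) holding ``raw_pct`` (no correction) and ``corrected_pct`` (startle
    movements blanked, then re-classified), plus the detected events.
    """
    events = detect_startle_events(trace, schedule, fparams, sparams)
    raw = classify_freezing(trace, fparams)
    corrected = classify_freezing(blank_startles(trace, events, schedule), fparams)
    rows = []
    for i, (a, b) in enumerate(schedule.cs_windows(), start=1):
        rows.append(
            {
                "cs_index": i,
                "raw_pct": window_percent_freezing(raw, a, b),
                "corrected_pct": window_percent_freezing(corrected, a, b),
            }
        )
    return pd.DataFrame(rows), events


def events_to_frame(events: list[StartleEvent]) -> pd.DataFrame:
    """Startle events as a table (beep_index, onset_s, duration_s, in_cs_period)."""
    return pd.DataFrame(
        [
            {
                "beep_index": ev.beep_index,
                "onset_s": ev.onset,
                "duration_s": ev.duration,
                "in_cs_period": ev.in_cs_period,
            }
            for ev in events
        ],
        columns=["beep_index", "onset_s", "duration_s", "in_cs_period"],
    )
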