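"""Session schedules for auditory fear/safety conditioning protocols.

A session is a fixed 1020-s timeline containing 30-s tone blocks (the CS:
30 beeps of 100 ms at 1 Hz, 7 kHz, 80 dB) and 1-s foot shocks (the US).
Protocol variants differ in which sessions they contain and in how CS and
US are arranged during training:

* ``safety_short`` — habituation, one explicitly-unpaired training session
  (variable 25-75 s CS-to-US interval, constant 60 s US-to-CS gap), one
  recall session in the training context (context A).
* ``us_only_short`` — identical, but training contains shocks only.
* ``fear_paired`` — CS and US paired (shock starts at the end of the last
  tone beep); recall in a novel context (context B).
* ``us_only_fear`` — the fear experiment's control: shocks only during
  training, recall in context B.
* ``unpaired_recall_B`` — explicitly-unpaired training, recall in context B.
* ``safety_prolonged`` / ``us_only_prolonged`` /
  ``us_only_prolonged_no_hab`` — five-session variants with two training
  and two recall sessions, five shocks per training session at reduced
  intensity (0.4 mA instead of 0.6 mA).

All times are continuous seconds from session onset; every interval is
half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ToneBlock",
    "ShockEvent",
    "SessionSchedule",
    "ProtocolSpec",
    "VARIANTS",
    "TABLE1_CS_STARTS",
    "TABLE1_US_STARTS",
    "build_schedule",
    "build_protocol",
    "cs_us_intervals",
    "us_cs_gaps",
    "validate_schedule",
    "schedule_to_dict",
    "schedule_from_dict",
    "export_event_table",
]

#: CS (tone block) onsets, seconds from session start, used in the
#: habituation, short-protocol training and all recall sessions.
TABLE1_CS_STARTS: tuple[float, ...] = (120.0, 265.0, 390.0, 555.0, 690.0, 805.0)

#: US (foot shock) onsets for explicitly-unpaired and US-only short training.
TABLE1_US_STARTS: tuple[float, ...] = (204.0, 329.0, 494.0, 629.0, 744.0, 899.0)

SESSION_DURATION_S = 1020.0

VARIANTS = (
    "safety_short",
    "us_only_short",
    "fear_paired",
    "us_only_fear",
    "unpaired_recall_B",
    "safety_prolonged",
    "us_only_prolonged",
    "us_only_prolonged_no_hab",
)

_PROLONGED_VARIANTS = frozenset(
    {"safety_prolonged", "us_only_prolonged", "us_only_prolonged_no_hab"}
)
_US_ONLY_VARIANTS = frozenset(
    {"us_only_short", "us_only_fear", "us_only_prolonged",
     "us_only_prolonged_no_hab"}
)

#: Seed for the jittered event times of the prolonged (two-training-session)
#: protocols, whose exact timings are generated rather than tabulated.
DEFAULT_PROLONGED_SEED = 73

#: Variable CS-end-to-US interval range, seconds, for unpaired training.
CS_US_INTERVAL_RANGE = (25.0, 75.0)
#: Constant US-end-to-next-CS gap, seconds, for unpaired training.
US_CS_GAP_S = 60.0


class ScheduleError(ValueError):
    """Raised for unknown variants or invalid variant/session combinations."""


@dataclass(frozen=True)
class ToneBlock:
    """A 30-s CS: a train of short tone beeps repeated at a fixed period."""

    start_time: float
    n_beeps: int = 30
    beep_duration: float = 0.1
    beep_period: float = 1.0
    carrier_hz: float = 7000.0
    level_db: float = 80.0
    rise_time: float = 0.005  # 0.002 in early experiments

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.n_beeps < 1:
            raise ValueError("n_beeps must be >= 1")
        if not self.beep_duration < self.beep_period:
            raise ValueError("beep_duration must be < beep_period")

    @property
    def nominal_duration(self) -> float:
        """Nominal block span in seconds (n_beeps x beep_period; 30 s default)."""
        return self.n_beeps * self.beep_period

    @property
    def end_time(self) -> float:
        """End of the nominal block window (half-open)."""
        return self.start_time + self.nominal_duration

    @property
    def last_beep_onset(self) -> float:
        return self.start_time + (self.n_beeps - 1) * self.beep_period

    @property
    def last_beep_offset(self) -> float:
        return self.last_beep_onset + self.beep_duration

    def beep_onsets(self) -> np.ndarray:
        """Onset time of every beep in the block."""
        return self.start_time + self.beep_period * np.arange(self.n_beeps)


@dataclass(frozen=True)
class ShockEvent:
    """A foot shock (US)."""

    start_time: float
    duration: float = 1.0
    intensity_ma: float = 0.6

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.intensity_ma <= 0:
            raise ValueError("intensity must be > 0")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class SessionSchedule:
    """Timed CS/US events within one fixed-duration session."""

    session_kind: str  # habituation | training | recall
    context: str  # "A" or "B"
    duration: float = SESSION_DURATION_S
    tone_blocks: tuple[ToneBlock, ...] = ()
    shocks: tuple[ShockEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tone_blocks", tuple(self.tone_blocks))
        object.__setattr__(self, "shocks", tuple(self.shocks))

    @property
    def n_samples(self) -> int:
        """Expected trace length at the standard 30 Hz video rate."""
        return int(round(self.duration * 30.0))

    def cs_windows(self) -> list[tuple[float, float]]:
        """Half-open [start, end) analysis window of each tone block."""
        return [(tb.start_time, tb.end_time) for tb in self.tone_blocks]

    def pre_cs_windows(self) -> list[tuple[float, float]]:
        """30-s baseline window immediately preceding each tone block."""
        return [
            (tb.start_time - tb.nominal_duration, tb.start_time)
            for tb in self.tone_blocks
        ]

    def beep_onsets(self) -> np.ndarray:
        """Onsets of every beep of every tone block, sorted."""
        if not self.tone_blocks:
            return np.empty(0)
        return np.concatenate([tb.beep_onsets() for tb in self.tone_blocks])


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered multi-day protocol; sessions are 24 +/- 1 h apart."""

    variant: str
    sessions: tuple[SessionSchedule, ...]
    inter_session_interval_h: float = 24.0

    def recall_sessions(self) -> list[SessionSchedule]:
        return [s for s in self.sessions if s.session_kind == "recall"]


def _tone_blocks(starts: Iterable[float], **kwargs) -> tuple[ToneBlock, ...]:
    return tuple(ToneBlock(start_time=float(s), **kwargs) for s in starts)


def _shocks(starts: Iterable[float], intensity: float) -> tuple[ShockEvent, ...]:
    return tuple(
        ShockEvent(start_time=float(s), intensity_ma=intensity) for s in starts
    )


def _prolonged_training_times(
    session_index: int, seed: int, n_shocks: int = 5
) -> tuple[list[float], list[float]]:
    """Jittered event times for a prolonged-protocol training session.

    The prolonged protocols keep the structural rules of the tabulated short
    protocol — a variable interval in [25, 75] s between the end of each CS
    (onset of its last beep) and the following US, and a constant 60 s gap
    between US offset and the next CS — but their exact onsets are not
    tabulated.  They are generated here deterministically from ``seed`` and
    the training-session ordinal, so both training sessions of one protocol
    differ while remaining reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, session_index]))
    lo, hi = CS_US_INTERVAL_RANGE
    cs_starts: list[float] = []
    us_starts: list[float] = []
    t = TABLE1_CS_STARTS[0]
    for _ in range(n_shocks):
        cs_starts.append(t)
        interval = float(rng.integers(int(lo), int(hi) + 1))
        us = (t + 29.0) + interval  # CS "end" = onset of the last beep
        us_starts.append(us)
        t = us + 1.0 + US_CS_GAP_S
    return cs_starts, us_starts


def build_schedule(
    variant: str,
    session_kind: str,
    session_index: int = 0,
    *,
    prolonged_seed: int = DEFAULT_PROLONGED_SEED,
    rise_time: float = 0.005,
) -> SessionSchedule:
    """Construct the fully timed schedule for one session of a protocol.

    Parameters
    ----------
    variant
        One of :data:`VARIANTS`.
    session_kind
        ``"habituation"``, ``"training"`` or ``"recall"``.
    session_index
        Ordinal among sessions of that kind (0-based); only the prolonged
        variants have more than one training/recall session.
    prolonged_seed
        Seed for the generated event times of prolonged training sessions.
    rise_time
        Tone beep rise time in seconds (0.005 default, 0.002 for the
        earliest experiments).
    """
    if variant not in VARIANTS:
        raise ScheduleError(f"unknown protocol variant: {variant!r}")
    prolonged = variant in _PROLONGED_VARIANTS
    us_only = variant in _US_ONLY_VARIANTS
    intensity = 0.4 if prolonged else 0.6
    tone_kw = dict(rise_time=rise_time)

    n_of_kind = {"habituation": 1, "training": 2 if prolonged else 1,
                 "recall": 2 if prolonged else 1}
    if session_kind not in n_of_kind:
        raise ScheduleError(f"unknown session kind: {session_kind!r}")
    if not 0 <= session_index < n_of_kind[session_kind]:
        raise ScheduleError(
            f"{variant} has {n_of_kind[session_kind]} {session_kind} "
            f"session(s); index {session_index} is invalid"
        )

    if session_kind == "habituation":
        blocks = (
            ()
            if variant == "us_only_prolonged_no_hab"
            else _tone_blocks(TABLE1_CS_STARTS, **tone_kw)
        )
        return SessionSchedule("habituation", "A", tone_blocks=blocks)

    if session_kind == "recall":
        context = (
            "B"
            if variant in ("fear_paired", "us_only_fear", "unpaired_recall_B")
            else "A"
        )
        return SessionSchedule(
            "recall", context, tone_blocks=_tone_blocks(TABLE1_CS_STARTS, **tone_kw)
        )

    # training
    if prolonged:
        cs_starts, us_starts = _prolonged_training_times(session_index, prolonged_seed)
        blocks = () if us_only else _tone_blocks(cs_starts, **tone_kw)
        return SessionSchedule(
            "training", "A", tone_blocks=blocks, shocks=_shocks(us_starts, intensity)
        )
    if variant == "fear_paired":
        blocks = _tone_blocks(TABLE1_CS_STARTS, **tone_kw)
        # paired: each shock starts at the offset of the last beep of its CS
        shock_starts = [tb.last_beep_offset for tb in blocks]
        return SessionSchedule(
            "training", "A", tone_blocks=blocks,
            shocks=_shocks(shock_starts, intensity),
        )
    blocks = () if us_only else _tone_blocks(TABLE1_CS_STARTS, **tone_kw)
    return SessionSchedule(
        "training", "A", tone_blocks=blocks,
        shocks=_shocks(TABLE1_US_STARTS, intensity),
    )


def build_protocol(
    variant: str,
    *,
    prolonged_seed: int = DEFAULT_PROLONGED_SEED,
    rise_time: float = 0.005,
) -> ProtocolSpec:
    """Assemble the full ordered session sequence for a protocol variant."""
    if variant not in VARIANTS:
        raise ScheduleError(f"unknown protocol variant: {variant!r}")
    prolonged = variant in _PROLONGED_VARIANTS
    kw = dict(prolonged_seed=prolonged_seed, rise_time=rise_time)
    sessions = [build_schedule(variant, "habituation", **kw)]
    n_train = 2 if prolonged else 1
    n_recall = 2 if prolonged else 1
    sessions += [build_schedule(variant, "training", i, **kw) for i in range(n_train)]
    sessions += [build_schedule(variant, "recall", i, **kw) for i in range(n_recall)]
    return ProtocolSpec(variant=variant, sessions=tuple(sessions))


def cs_us_intervals(schedule: SessionSchedule) -> list[float]:
    """Interval from the end of each CS to the following US, in seconds.

    "End of CS" is the onset of the block's last beep (start + 29 s for the
    default 30-beep/1-Hz block): this is the convention under which the
    tabulated short-protocol times yield the published interval column
    [55, 35, 75, 45, 25, 65] s.  Each US is attributed to the latest CS
    starting before it.
    """
    pairs = []
    for us in schedule.shocks:
        preceding = [tb for tb in schedule.tone_blocks if tb.start_time < us.start_time]
        if preceding:
            cs = max(preceding, key=lambda tb: tb.start_time)
            pairs.append(us.start_time - cs.last_beep_onset)
    if not pairs:
        raise ScheduleError("schedule contains no CS followed by a US")
    return pairs


def us_cs_gaps(schedule: SessionSchedule) -> list[float]:
    """Gap from each US offset to the next CS onset, in seconds."""
    gaps = []
    for us in schedule.shocks:
        following = [
            tb for tb in schedule.tone_blocks if tb.start_time >= us.end_time
        ]
        if following:
            cs = min(following, key=lambda tb: tb.start_time)
            gaps.append(cs.start_time - us.end_time)
    if not gaps:
        raise ScheduleError("schedule contains no US followed by a CS")
    return gaps


def validate_schedule(schedule: SessionSchedule) -> list[str]:
    """Check structural invariants; returns human-readable violations.

    Never raises: an empty list means the schedule is valid.
    """
    v: list[str] = []
    if schedule.context not in ("A", "B"):
        v.append(f"context must be 'A' or 'B', got {schedule.context!r}")
    if schedule.session_kind not in ("habituation", "training", "recall"):
        v.append(f"unknown session_kind {schedule.session_kind!r}")
    blocks = schedule.tone_blocks
    for i, tb in enumerate(blocks):
        if tb.end_time > schedule.duration:
            v.append(
                f"tone block {i} ends at {tb.end_time} s, beyond the "
                f"{schedule.duration} s session"
            )
    for i in range(1, len(blocks)):
        if blocks[i].start_time < blocks[i - 1].start_time:
            v.append(f"tone blocks {i - 1} and {i} are out of order")
        elif blocks[i].start_time < blocks[i - 1].end_time:
            v.append(f"tone blocks {i - 1} and {i} overlap")
    shocks = schedule.shocks
    for i, us in enumerate(shocks):
        if us.end_time > schedule.duration:
            v.append(
                f"shock {i} ends at {us.end_time} s, beyond the "
                f"{schedule.duration} s session"
            )
    for i in range(1, len(shocks)):
        if shocks[i].start_time < shocks[i - 1].start_time:
            v.append(f"shocks {i - 1} and {i} are out of order")
    if schedule.session_kind in ("habituation", "recall") and shocks:
        v.append(f"{schedule.session_kind} session must not contain shocks")
    return v


# ---------------------------------------------------------------------------
# serialization

def schedule_to_dict(schedule: SessionSchedule) -> dict:
    return {
        "session_kind": schedule.session_kind,
        "context": schedule.context,
        "duration": schedule.duration,
        "tone_blocks": [asdict(tb) for tb in schedule.tone_blocks],
        "shocks": [asdict(us) for us in schedule.shocks],
    }


def schedule_from_dict(d: dict) -> SessionSchedule:
    return SessionSchedule(
        session_kind=d["session_kind"],
        context=d["context"],
        duration=float(d.get("duration", SESSION_DURATION_S)),
        tone_blocks=tuple(ToneBlock(**tb) for tb in d.get("tone_blocks", [])),
        shocks=tuple(ShockEvent(**us) for us in d.get("shocks", [])),
    )


def save_schedule(schedule: SessionSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


def load_schedule(path) -> SessionSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))


def export_event_table(schedule: SessionSchedule, path) -> None:
    """Write the schedule as a flat plain-text event table (CSV)."""
    rows = []
    for tb in schedule.tone_blocks:
        rows.append(
            (
                "tone_block",
                tb.start_time,
                tb.nominal_duration,
                f"n_beeps={tb.n_beeps};carrier_hz={tb.carrier_hz:g};"
                f"level_db={tb.level_db:g}",
            )
        )
    for us in schedule.shocks:
        rows.append(
            ("shock", us.start_time, us.duration, f"intensity_ma={us.intensity_ma:g}")
        )
    rows.sort(key=lambda r: r[1])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_type", "start_s", "duration_s", "params"])
        w.writerows(rows)
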