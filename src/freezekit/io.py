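"""File formats and run configuration.

All artifacts are plain CSV.  The movement-trace dialect has a header and
columns ``frame`` (integer, 0-based, strictly increasing by 1), ``time_s``
(= frame / sample_rate) and ``motion`` (arbitrary units, >= 0), one file
per mouse-session.  Times are always serialized in seconds with the
sample rate stated explicitly, never as bare frame counts, to avoid
0/1-based ambiguity across tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .freezing import (
    BinnedFreezing,
    FreezingParams,
    FreezingTrace,
    MovementTrace,
    SAMPLE_RATE_HZ,
)
from .startle import StartleParams

__all__ = [
    "TraceDialectError",
    "read_trace",
    "write_trace",
    "write_freezing",
    "write_binned",
    "RunConfig",
]


class TraceDialectError(ValueError):
    """A trace file violates the movement-trace CSV dialect."""


def write_trace(trace: MovementTrace, path) -> None:
    """Write a movement trace in the standard CSV dialect (6-decimal)."""
    frames = np.arange(trace.n_samples)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames / trace.sample_rate,
            "motion": trace.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(
    path,
    sample_rate: float = SAMPLE_RATE_HZ,
    *,
    mouse_id: str = "",
    session_id: str = "",
) -> MovementTrace:
    """Read a movement trace, validating the dialect.

    Raises :class:`TraceDialectError` on missing columns, non-contiguous
    frame numbers (naming the first bad row), inconsistent time stamps or
    negative motion values.
    """
    df = pd.read_csv(path)
    missing = {"frame", "time_s", "motion"} - set(df.columns)
    if missing:
        raise TraceDialectError(
            f"{path}: missing column(s) {', '.join(sorted(missing))}"
        )
    frames = df["frame"].to_numpy()
    expected = np.arange(len(frames))
    bad = np.flatnonzero(frames != expected)
    if bad.size:
        r = int(bad[0])
        raise TraceDialectError(
            f"{path}: row {r}: frame {frames[r]} where {expected[r]} expected "
            "(frames must start at 0 and increase by 1)"
        )
    times = df["time_s"].to_numpy()
    if np.abs(times - frames / sample_rate).max(initial=0.0) > 1e-6:
        raise TraceDialectError(
            f"{path}: time_s does not equal frame / {sample_rate:g} within 1e-6"
        )
    motion = df["motion"].to_numpy(dtype=float)
    if motion.size and motion.min() < 0:
        raise TraceDialectError(f"{path}: negative motion values")
    return MovementTrace(motion, sample_rate, mouse_id=mouse_id,
                         session_id=session_id)


def write_freezing(freezing: FreezingTrace, path) -> None:
    frames = np.arange(freezing.n_samples)
    pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames / freezing.sample_rate,
            "freezing": freezing.states,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_binned(binned: BinnedFreezing, path) -> None:
    edges = binned.bin_edges()
    pd.DataFrame(
        {
            "bin_start_s": edges[:-1],
            "bin_end_s": edges[1:],
            "percent_freezing": binned.values,
        }
    ).to_csv(path, index=False, float_format="%.6f")


@dataclass
class RunConfig:
    """Resolved configuration of an analysis run.

    Every run writes its resolved config beside its outputs so any result
    can be regenerated from the saved file alone.
    """

    variant: str = "us_only_short"
    n_mice: int = 5
    master_seed: int = 0
    group: str = "US-only"
    freezing: FreezingParams = field(default_factory=FreezingParams)
    startle: StartleParams = field(default_factory=StartleParams)
    behavior: dict = field(default_factory=dict)  # BehaviorParams overrides
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "freezing" in d and isinstance(d["freezing"], dict):
            d["freezing"] = FreezingParams(**d["freezing"])
        if "startle" in d and isinstance(d["startle"], dict):
            d["startle"] = StartleParams(**d["startle"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
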