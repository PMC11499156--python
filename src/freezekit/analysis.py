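"""Window-based analysis: preCS/CS tables, differences, group summaries,
and the external-inhibition-vs-contextual-freezing pairing.

For each tone block the 30 s immediately before its onset is the "preCS"
baseline window and the block itself the "CS" window.  The CS-induced
freezing difference per mouse and block is (startle-corrected CS percent
freezing) - (preCS percent freezing); preCS values are never startle
corrected.  External inhibition is the tone-induced *reduction* of
freezing, i.e. the negated difference, and is paired with the group-mean
preCS freezing to quantify how suppression scales with ongoing contextual
freezing.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .freezing import FreezingParams, MovementTrace, classify_freezing, \
    window_percent_freezing
from .protocol import SessionSchedule
from .startle import StartleParams, corrected_cs_freezing

logger = logging.getLogger(__name__)

__all__ = [
    "compute_window_table",
    "per_mouse_mean_difference",
    "group_summary",
    "build_inhibition_points",
]

WINDOW_COLUMNS = [
    "mouse_id",
    "group",
    "session_id",
    "cs_index",
    "pre_cs_pct",
    "cs_pct_raw",
    "cs_pct_corrected",
    "difference",
]


def compute_window_table(
    traces: Mapping[str, MovementTrace],
    schedule: SessionSchedule,
    fparams: FreezingParams = FreezingParams(),
    sparams: StartleParams = StartleParams(),
    *,
    group: str = "",
    session_id: str = "",
) -> pd.DataFrame:
    """One record per mouse x tone block with preCS/CS freezing percents.

    ``traces`` maps mouse id to the session's movement trace.  CS values
    are reported both raw and startle-corrected; the difference column is
    corrected CS minus preCS.  Windows that cannot be evaluated propagate
    as missing records with a logged warning.
    """
    pre_windows = schedule.pre_cs_windows()
    for a, _ in pre_windows:
        if a < 0:
            raise ValueError("a preCS window extends before session start")
    rows = []
    for mouse_id, trace in traces.items():
        freezing = classify_freezing(trace, fparams)
        per_cs, _events = corrected_cs_freezing(trace, schedule, fparams, sparams)
        for i, (a, b) in enumerate(pre_windows, start=1):
            try:
                pre = window_percent_freezing(freezing, a, b)
            except ValueError:
                logger.warning(
                    "mouse %s: preCS window %d outside trace; record dropped",
                    mouse_id, i,
                )
                continue
            cs_row = per_cs.loc[per_cs["cs_index"] == i].iloc[0]
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "group": group,
                    "session_id": session_id or trace.session_id,
                    "cs_index": i,
                    "pre_cs_pct": pre,
                    "cs_pct_raw": cs_row["raw_pct"],
                    "cs_pct_corrected": cs_row["corrected_pct"],
                    "difference": cs_row["corrected_pct"] - pre,
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def per_mouse_mean_difference(table: pd.DataFrame) -> pd.Series:
    """Mean CS-induced difference across all tone blocks, per mouse.

    Requires the same complete set of CS indices for every mouse (the
    standard session has six).
    """
    counts = table.groupby("mouse_id")["cs_index"].count()
    expected = table["cs_index"].nunique()
    missing = counts[counts != expected]
    if not missing.empty:
        raise ValueError(
            f"mice with incomplete CS records: {', '.join(missing.index)}"
        )
    return table.groupby("mouse_id")["difference"].mean()


def group_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-CS mean +/- SEM of the difference, and per-mouse means.

    SEM is the sample standard deviation (ddof=1) divided by sqrt(N mice).
    """
    per_cs = (
        table.groupby("cs_index")["difference"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)), n="count")
        .reset_index()
    )
    return per_cs, per_mouse_mean_difference(table)


def build_inhibition_points(
    tables: list[pd.DataFrame],
    *,
    require_us_only: bool = True,
) -> pd.DataFrame:
    """External-inhibition points from US-only recall window tables.

    Each input table is one (group, recall session) window table.  For
    every (group, session, cs_index) the across-mouse mean preCS percent
    freezing is paired with the across-mouse mean tone-induced *reduction*
    of freezing (negated difference).  Points are pooled across
    experiments so the preCS-freezing/inhibition relation can be assessed
    by correlation.

    With ``require_us_only`` (default) a table whose group label does not
    contain "US-only" (case-insensitive, hyphen/underscore agnostic) is
    rejected: mice with tone experience during training would confound the
    external-inhibition readout with learned effects.
    """
    frames = []
    for table in tables:
        if table.empty:
            continue
        if require_us_only:
            labels = {
                str(g).lower().replace("-", "").replace("_", "").replace(" ", "")
                for g in table["group"].unique()
            }
            if any("usonly" not in g for g in labels):
                raise ValueError(
                    "build_inhibition_points expects US-only group tables; got "
                    + ", ".join(sorted(map(str, table["group"].unique())))
                )
        agg = (
            table.groupby(["group", "session_id", "cs_index"], observed=True)
            .agg(mean_pre_cs_pct=("pre_cs_pct", "mean"),
                 mean_difference=("difference", "mean"),
                 n_mice=("mouse_id", "nunique"))
            .reset_index()
        )
        agg["inhibition"] = -agg.pop("mean_difference")
        frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=["group", "session_id", "cs_index", "mean_pre_cs_pct",
                     "n_mice", "inhibition"]
        )
    return pd.concat(frames, ignore_index=True)
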