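"""Seeded simulator for per-mouse movement-index traces with ground truth.

The generative model is a two-state (active / frozen) continuous-time
Markov chain sampled at the 30 Hz video rate, the minimal model that
reproduces the behavioral structure the pipeline must handle:

* little freezing during habituation;
* during training, the freezing-entry hazard grows with each delivered
  foot shock (contextual fear build-up), and each shock forces the animal
  into a running/jumping burst (active state) for a fixed period;
* during recall, the entry hazard ramps to a plateau so that contextual
  freezing reaches its asymptote within ~100 s — high in the training
  context (A), lower "residual" freezing in a novel context (B);
* during the 30-s CS periods the freezing-exit hazard is boosted in
  proportion to the current local freezing level (external inhibition:
  tone-evoked movement initiation whose impact scales with ongoing
  freezing), and the entry hazard can be multiplied by a learned-fear
  factor (CS+ recall);
* while frozen, individual tone beeps can evoke short startle transients:
  supra-threshold excursions of the movement index that do not change the
  underlying behavioral state.

Movement-index values are drawn per state from log-normal distributions
that straddle the 40 a.u. classifier threshold with negligible overlap
(~1e-4 misclassification per sample), so the thresholded state tracks the
ground-truth state almost exactly.  All randomness flows from a single
seed; a master-seed -> per-mouse-session derivation via
``numpy.random.SeedSequence([master, mouse_index, session_index])`` makes
any single mouse reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .freezing import MovementTrace, SAMPLE_RATE_HZ
from .protocol import ProtocolSpec, SessionSchedule

__all__ = [
    "BehaviorParams",
    "SyntheticGroundTruth",
    "ExperimentData",
    "simulate_mouse_session",
    "simulate_experiment",
    "simulate_us_only_inhibition_study",
    "US_ONLY_STUDY_LAYOUT",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the behavioral generator.

    Hazard rates are per second; the chain is sampled at 30 Hz with exact
    per-step transition probabilities ``1 - exp(-rate * dt)``.
    """

    # state-conditional movement-index distributions (log-normal); the
    # defaults put ~5 log-sd between each state's median and the 40 a.u.
    # threshold, so per-sample misclassification is ~1e-8 and the
    # thresholded state equals the ground-truth state in practice
    freeze_index_median: float = 8.0
    freeze_index_sigma: float = 0.30
    active_index_median: float = 200.0
    active_index_sigma: float = 0.35

    # habituation-phase hazards (low freezing)
    hab_entry_rate: float = 0.006
    hab_exit_rate: float = 0.15

    # training phase: entry hazard = base + gain * shocks delivered so far
    entry_base_rate: float = 0.01
    contextual_gain: float = 0.048
    exit_rate: float = 0.15
    post_shock_burst: float = 12.0  # s of forced activity after each shock

    # recall phase: entry hazard ramps to the plateau-occupancy level
    recall_plateau: float = 70.0  # percent freezing asymptote, context A
    recall_plateau_novel: float = 30.0  # residual freezing, context B
    recall_rise_tau: float = 30.0  # s; plateau reached within ~100 s

    # CS-period modulation
    inhibition_slope: float = 4.0  # k: exit-rate boost per unit local freezing
    learned_fear_boost: float = 1.0  # entry-rate multiplier (CS+ recall > 1)
    safety_effect: float = 0.0  # additional CS-period exit-rate boost
    feedback_tau: float = 30.0  # s; EMA window defining "local freezing"

    # beep-locked startle transients
    startle_prob: float = 0.3  # per beep, while frozen
    startle_onset_window: float = 0.2  # s after beep onset
    startle_duration_range: tuple[float, float] = (0.15, 0.30)  # s, < 0.9

    def __post_init__(self) -> None:
        for name in (
            "hab_entry_rate", "hab_exit_rate", "entry_base_rate",
            "contextual_gain", "exit_rate", "inhibition_slope",
            "safety_effect", "post_shock_burst",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.startle_prob <= 1:
            raise ValueError("startle_prob must be in [0, 1]")
        lo, hi = self.startle_duration_range
        if not 0 < lo <= hi < 0.9:
            raise ValueError("startle durations must lie within (0, 0.9) s")
        for name in ("recall_plateau", "recall_plateau_novel"):
            if not 0 <= getattr(self, name) < 100:
                raise ValueError(f"{name} must be in [0, 100) percent")
        if self.learned_fear_boost < 0:
            raise ValueError("learned_fear_boost must be >= 0")
        if self.recall_rise_tau <= 0 or self.feedback_tau <= 0:
            raise ValueError("time constants must be > 0")

    def recall_entry_plateau(self, context: str) -> float:
        """Entry hazard giving the context's plateau occupancy at fixed exit."""
        f = (self.recall_plateau if context == "A" else self.recall_plateau_novel)
        f /= 100.0
        return self.exit_rate * f / (1.0 - f)

    @staticmethod
    def stationary(rate: float = 0.25) -> "BehaviorParams":
        """Parameters giving a time-homogeneous chain with occupancy 50%.

        With equal entry and exit hazards everywhere and no CS effects or
        startles, the closed-form stationary occupancy of the two-state
        chain is exactly 1/2 — the reference point for parameter-recovery
        checks.
        """
        return BehaviorParams(
            hab_entry_rate=rate,
            hab_exit_rate=rate,
            inhibition_slope=0.0,
            startle_prob=0.0,
        )


@dataclass(frozen=True)
class InjectedStartle:
    beep_index: int
    start_sample: int
    n_samples: int

    @property
    def onset(self) -> float:
        return self.start_sample / SAMPLE_RATE_HZ

    @property
    def duration(self) -> float:
        return self.n_samples / SAMPLE_RATE_HZ


@dataclass
class SyntheticGroundTruth:
    """The simulator's true state sequence and injected artifacts."""

    states: np.ndarray  # per-sample, 1 = frozen
    startles: list[InjectedStartle]
    params: BehaviorParams
    sample_rate: float = SAMPLE_RATE_HZ

    def occupancy_pct(self) -> float:
        """True percent time frozen over the whole session."""
        return 100.0 * float(self.states.mean())

    def window_pct(self, start_s: float, end_s: float) -> float:
        """True percent time frozen over a half-open window."""
        fs = self.sample_rate
        i0 = int(math.ceil(start_s * fs - 1e-9))
        i1 = int(math.ceil(end_s * fs - 1e-9))
        return 100.0 * float(self.states[i0:i1].mean())


# ---------------------------------------------------------------------------
# chain simulation

def _simulate_states_py(entry_p, exit_base, forced_active, in_cs, k, safety,
                        alpha, dt, u):
    n = entry_p.shape[0]
    states = np.zeros(n, dtype=np.uint8)
    state = 0
    f_ema = 0.0
    for t in range(n):
        if forced_active[t]:
            state = 0
        elif state == 0:
            if u[t] < entry_p[t]:
                state = 1
        else:
            rate = exit_base[t]
            if in_cs[t]:
                rate *= 1.0 + k * f_ema + safety
            if u[t] < -math.expm1(-rate * dt):
                state = 0
        states[t] = state
        f_ema += alpha * (state - f_ema)
    return states


try:  # pragma: no cover - exercised implicitly
    import numba

    _simulate_states = numba.njit(cache=True)(_simulate_states_py)
except Exception:  # pragma: no cover
    _simulate_states = _simulate_states_py


def _session_hazards(
    params: BehaviorParams,
    schedule: SessionSchedule,
    n: int,
    fs: float,
    prev_shocks: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample entry hazard, exit hazard, forced-active and in-CS masks."""
    t = np.arange(n) / fs
    kind = schedule.session_kind
    if kind == "habituation":
        entry = np.full(n, params.hab_entry_rate)
        exit_ = np.full(n, params.hab_exit_rate)
    elif kind == "training":
        shocks_so_far = np.zeros(n)
        for us in schedule.shocks:
            shocks_so_far[t >= us.end_time] += 1
        entry = params.entry_base_rate + params.contextual_gain * (
            prev_shocks + shocks_so_far
        )
        exit_ = np.full(n, params.exit_rate)
    elif kind == "recall":
        plateau = params.recall_entry_plateau(schedule.context)
        entry = plateau * -np.expm1(-t / params.recall_rise_tau)
        exit_ = np.full(n, params.exit_rate)
    else:
        raise ValueError(f"unknown session kind {kind!r}")

    forced = np.zeros(n, dtype=bool)
    for us in schedule.shocks:
        a = int(math.ceil(us.start_time * fs - 1e-9))
        b = int(math.ceil((us.end_time + params.post_shock_burst) * fs - 1e-9))
        forced[a:min(b, n)] = True

    in_cs = np.zeros(n, dtype=bool)
    for a, b in schedule.cs_windows():
        i0 = int(math.ceil(a * fs - 1e-9))
        i1 = int(math.ceil(b * fs - 1e-9))
        in_cs[i0:min(i1, n)] = True
    entry = entry.copy()
    entry[in_cs] *= params.learned_fear_boost
    return entry, exit_, forced, in_cs


def _inject_startles(
    states: np.ndarray,
    schedule: SessionSchedule,
    params: BehaviorParams,
    fs: float,
    rng: np.random.Generator,
) -> list[InjectedStartle]:
    """Choose beep-locked startle transients compatible with the state path.

    A startle is only injected when the mouse is stably frozen — at least
    half a second of immobility on both sides of the transient — so the
    injected supra-threshold excursion forms an isolated movement run that
    starts within the onset window and punctures an otherwise continuous
    freezing bout, the phenomenon observed on real movement traces.
    """
    if params.startle_prob == 0 or not schedule.tone_blocks:
        return []
    beeps = schedule.beep_onsets()
    n = states.size
    lo_s = max(1, int(round(params.startle_duration_range[0] * fs)))
    hi_s = int(round(params.startle_duration_range[1] * fs))
    onset_max = int(math.floor(params.startle_onset_window * fs + 1e-9))
    pad = int(math.ceil(0.5 * fs))  # stable-immobility margin, samples
    out: list[InjectedStartle] = []
    for b_idx, b in enumerate(beeps):
        if rng.random() >= params.startle_prob:
            continue
        ib = int(round(b * fs))
        off = int(rng.integers(0, onset_max + 1))
        dur = int(rng.integers(lo_s, hi_s + 1))
        start = ib + off
        end = start + dur
        if ib - pad < 0 or end + pad > n:
            continue
        if np.all(states[ib - pad : end + pad] == 1):
            out.append(InjectedStartle(b_idx, start, dur))
    return out


def simulate_mouse_session(
    params: BehaviorParams,
    schedule: SessionSchedule,
    seed,
    *,
    prev_shocks: int = 0,
    mouse_id: str = "",
    session_id: str = "",
) -> tuple[MovementTrace, SyntheticGroundTruth]:
    """Simulate one mouse-session: movement trace plus ground truth.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.
    ``prev_shocks`` carries the cumulative shock count from earlier
    training sessions so contextual fear persists across days in
    multi-training protocols.
    """
    rng = np.random.default_rng(seed)
    fs = SAMPLE_RATE_HZ
    n = schedule.n_samples
    entry, exit_, forced, in_cs = _session_hazards(
        params, schedule, n, fs, prev_shocks
    )
    dt = 1.0 / fs
    entry_p = -np.expm1(-entry * dt)
    u = rng.random(n)
    states = _simulate_states(
        entry_p,
        exit_,
        forced,
        in_cs,
        float(params.inhibition_slope),
        float(params.safety_effect),
        dt / params.feedback_tau,
        dt,
        u,
    )
    startles = _inject_startles(states, schedule, params, fs, rng)

    frozen_draws = params.freeze_index_median * np.exp(
        params.freeze_index_sigma * rng.standard_normal(n)
    )
    active_draws = params.active_index_median * np.exp(
        params.active_index_sigma * rng.standard_normal(n)
    )
    values = np.where(states == 1, frozen_draws, active_draws)
    for ev in startles:
        sl = slice(ev.start_sample, ev.start_sample + ev.n_samples)
        values[sl] = active_draws[sl]
    trace = MovementTrace(values, fs, mouse_id=mouse_id, session_id=session_id)
    truth = SyntheticGroundTruth(states=states, startles=startles, params=params)
    return trace, truth


@dataclass
class ExperimentData:
    """A simulated cohort: traces and ground truth per mouse-session."""

    protocol: ProtocolSpec
    group: str
    traces: dict[tuple[str, int], MovementTrace]  # (mouse_id, session index)
    truths: dict[tuple[str, int], SyntheticGroundTruth]
    metadata: pd.DataFrame  # mouse_id, group, session_index, session_kind, seed

    def session_traces(self, session_index: int) -> dict[str, MovementTrace]:
        return {
            m: tr for (m, s), tr in self.traces.items() if s == session_index
        }


def simulate_experiment(
    protocol: ProtocolSpec,
    n_mice: int,
    params: BehaviorParams,
    master_seed: int,
    *,
    group: str = "",
    mouse_prefix: str = "m",
) -> ExperimentData:
    """Simulate every session of a protocol for a cohort of mice.

    Each mouse-session gets an independent seed derived as
    ``SeedSequence([master_seed, mouse_index, session_index])``.  Training
    sessions accumulate delivered shocks per mouse, so later sessions
    start from an elevated contextual-fear level.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    traces: dict[tuple[str, int], MovementTrace] = {}
    truths: dict[tuple[str, int], SyntheticGroundTruth] = {}
    meta = []
    for mi in range(n_mice):
        mouse_id = f"{mouse_prefix}{mi:02d}"
        prev_shocks = 0
        for si, schedule in enumerate(protocol.sessions):
            ss = np.random.SeedSequence([master_seed, mi, si])
            sid = f"{schedule.session_kind}{si}"
            trace, truth = simulate_mouse_session(
                params,
                schedule,
                ss,
                prev_shocks=prev_shocks,
                mouse_id=mouse_id,
                session_id=sid,
            )
            traces[(mouse_id, si)] = trace
            truths[(mouse_id, si)] = truth
            if schedule.session_kind == "training":
                prev_shocks += len(schedule.shocks)
            meta.append(
                {
                    "mouse_id": mouse_id,
                    "group": group,
                    "session_index": si,
                    "session_kind": schedule.session_kind,
                    "context": schedule.context,
                    "seed_entropy": f"[{master_seed}, {mi}, {si}]",
                }
            )
    return ExperimentData(
        protocol=protocol,
        group=group,
        traces=traces,
        truths=truths,
        metadata=pd.DataFrame(meta),
    )


#: The four US-only control experiments that feed the external-inhibition
#: correlation: (protocol variant, cohort size, group label).  Cohort sizes
#: mirror the study design (N = 5, 6, 6 and 5 mice); the two prolonged
#: protocols contribute two recall sessions each, giving
#: 6 + 12 + 12 + 6 = 36 group-averaged points.
US_ONLY_STUDY_LAYOUT: tuple[tuple[str, int, str], ...] = (
    ("us_only_short", 5, "US-only 3d"),
    ("us_only_prolonged", 6, "US-only 5d"),
    ("us_only_prolonged_no_hab", 6, "US-only 5d no-hab"),
    ("us_only_fear", 5, "US-only fear"),
)


def simulate_us_only_inhibition_study(
    master_seed: int,
    params: BehaviorParams | None = None,
) -> list[pd.DataFrame]:
    """Recall-session window tables of the pooled US-only experiments.

    Simulates the recall sessions of the four US-only control cohorts
    (:data:`US_ONLY_STUDY_LAYOUT`) and returns one preCS/CS window table
    per (cohort, recall session), ready for
    :func:`freezekit.analysis.build_inhibition_points`.  Only recall
    sessions are simulated: the recall-phase hazards are parameterized
    directly, so training sessions do not influence them.
    """
    from .analysis import compute_window_table
    from .protocol import build_protocol

    params = params or BehaviorParams()
    tables: list[pd.DataFrame] = []
    for li, (variant, n_mice, label) in enumerate(US_ONLY_STUDY_LAYOUT):
        proto = build_protocol(variant)
        recalls = [
            (si, s) for si, s in enumerate(proto.sessions)
            if s.session_kind == "recall"
        ]
        for si, sched in recalls:
            traces = {}
            for mi in range(n_mice):
                ss = np.random.SeedSequence([master_seed, li, mi, si])
                trace, _ = simulate_mouse_session(
                    params, sched, ss, mouse_id=f"m{mi:02d}"
                )
                traces[f"m{mi:02d}"] = trace
            tables.append(
                compute_window_table(
                    traces, sched, group=label, session_id=f"recall{si}"
                )
            )
    return tables
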