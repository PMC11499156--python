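"""Simulator contracts: determinism, stationary occupancy, startle
injection, phenomenology, and parameter recovery through the pipeline."""

import numpy as np
import pytest

import freezekit as fk
from freezekit.protocol import SessionSchedule, build_protocol, build_schedule
from freezekit.synthetic_data import (
    BehaviorParams,
    simulate_experiment,
    simulate_mouse_session,
)

FS = 30.0


@pytest.fixture(scope="module")
def plain_context() -> SessionSchedule:
    """A tone-free session for stationary-chain checks."""
    return SessionSchedule("habituation", "A")


class TestDeterminism:
    def test_same_seed_gives_identical_traces(self, recall_schedule):
        p = BehaviorParams()
        t1, g1 = simulate_mouse_session(p, recall_schedule, 42)
        t2, g2 = simulate_mouse_session(p, recall_schedule, 42)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(g1.states, g2.states)
        assert g1.startles == g2.startles

    def test_different_seeds_differ(self, recall_schedule):
        p = BehaviorParams()
        t1, _ = simulate_mouse_session(p, recall_schedule, 1)
        t2, _ = simulate_mouse_session(p, recall_schedule, 2)
        assert not np.array_equal(t1.values, t2.values)

    def test_experiment_mouse_isolation(self, ):
        """A single mouse-session is reproducible from the documented
        SeedSequence([master, mouse, session]) derivation alone."""
        proto = build_protocol("us_only_short")
        data = simulate_experiment(proto, 2, BehaviorParams(), 7, group="US-only")
        trace = data.traces[("m01", 2)]
        ss = np.random.SeedSequence([7, 1, 2])
        solo, _ = simulate_mouse_session(BehaviorParams(), proto.sessions[2], ss)
        np.testing.assert_array_equal(trace.values, solo.values)


class TestChainBehavior:
    def test_zero_entry_rate_gives_zero_freezing(self, plain_context):
        p = BehaviorParams(hab_entry_rate=0.0, startle_prob=0.0)
        trace, truth = simulate_mouse_session(p, plain_context, 3)
        assert truth.occupancy_pct() == 0.0
        est = fk.classify_freezing(trace)
        assert est.states.sum() == 0

    def test_stationary_occupancy_recovered_by_pipeline(self, plain_context):
        """entry = exit => closed-form occupancy 1/2; the pipeline estimate
        over a cohort lands within 2 pp."""
        p = BehaviorParams.stationary(0.25)
        ests, truths = [], []
        for seed in range(16):
            trace, truth = simulate_mouse_session(p, plain_context, seed)
            ests.append(100.0 * fk.classify_freezing(trace).states.mean())
            truths.append(truth.occupancy_pct())
        assert abs(np.mean(ests) - 50.0) < 2.0
        assert abs(np.mean(truths) - 50.0) < 2.0

    def test_pipeline_tracks_ground_truth_occupancy(self, recall_schedule):
        """Startle-free full-session estimate within 2 pp of the true state
        occupancy, per session."""
        p = BehaviorParams(startle_prob=0.0)
        for seed in range(5):
            trace, truth = simulate_mouse_session(p, recall_schedule, seed)
            est = 100.0 * fk.classify_freezing(trace).states.mean()
            assert abs(est - truth.occupancy_pct()) < 2.0

    def test_habituation_freezing_is_low(self):
        sched = build_schedule("safety_short", "habituation")
        p = BehaviorParams(startle_prob=0.0)
        trace, truth = simulate_mouse_session(p, sched, 11)
        assert truth.occupancy_pct() < 20.0

    def test_training_freezing_builds_up_across_shocks(self):
        sched = build_schedule("us_only_short", "training")
        p = BehaviorParams(startle_prob=0.0)
        occ_early, occ_late = [], []
        for seed in range(8):
            _, truth = simulate_mouse_session(p, sched, seed)
            occ_early.append(truth.window_pct(0.0, 200.0))
            occ_late.append(truth.window_pct(900.0, 1020.0))
        assert np.mean(occ_late) > np.mean(occ_early) + 20.0

    def test_post_shock_burst_forces_activity(self):
        sched = build_schedule("us_only_short", "training")
        p = BehaviorParams(startle_prob=0.0)
        _, truth = simulate_mouse_session(p, sched, 4)
        for us in sched.shocks:
            assert truth.window_pct(us.start_time,
                                    us.end_time + p.post_shock_burst) == 0.0

    def test_recall_reaches_plateau_within_100s(self, recall_schedule):
        p = BehaviorParams(startle_prob=0.0, inhibition_slope=0.0)
        occ = []
        for seed in range(10):
            _, truth = simulate_mouse_session(p, recall_schedule, seed)
            occ.append([truth.window_pct(100.0, 120.0),
                        truth.window_pct(0.0, 30.0)])
        plateau_est = np.mean([o[0] for o in occ])
        early = np.mean([o[1] for o in occ])
        assert abs(plateau_est - p.recall_plateau) < 12.0
        # freezing is still building during the first 30 s of the session
        assert early < plateau_est - 20.0

    def test_novel_context_residual_freezing_lower(self):
        recall_a = build_schedule("us_only_short", "recall")
        recall_b = build_schedule("us_only_fear", "recall")
        p = BehaviorParams(startle_prob=0.0, inhibition_slope=0.0)
        occ_a = np.mean([simulate_mouse_session(p, recall_a, s)[1].occupancy_pct()
                         for s in range(6)])
        occ_b = np.mean([simulate_mouse_session(p, recall_b, s)[1].occupancy_pct()
                         for s in range(6)])
        assert occ_b < occ_a - 20.0


class TestCsModulation:
    def test_null_parameters_make_cs_statistically_plain(self, recall_schedule):
        """k = 0, no fear boost, no safety effect: per-mouse mean CS-induced
        differences are centered on 0 (sign test over 100 seeds)."""
        from scipy.stats import binomtest

        p = BehaviorParams(inhibition_slope=0.0, learned_fear_boost=1.0,
                           safety_effect=0.0, startle_prob=0.0)
        diffs = []
        for seed in range(100):
            trace, _ = simulate_mouse_session(p, recall_schedule, seed)
            table = fk.compute_window_table({"m0": trace}, recall_schedule)
            diffs.append(table["difference"].mean())
        diffs = np.asarray(diffs)
        n_pos = int((diffs > 0).sum())
        n_nonzero = int((diffs != 0).sum())
        assert binomtest(n_pos, n_nonzero).pvalue > 0.05

    def test_inhibition_suppresses_cs_freezing(self, recall_schedule):
        p = BehaviorParams(startle_prob=0.0)  # k = 4 default
        diffs = []
        for seed in range(10):
            trace, _ = simulate_mouse_session(p, recall_schedule, seed)
            table = fk.compute_window_table({"m0": trace}, recall_schedule)
            diffs.append(table["difference"].mean())
        assert np.mean(diffs) < -5.0

    def test_learned_fear_boost_raises_cs_freezing_in_novel_context(self):
        recall_b = build_schedule("fear_paired", "recall")
        p = BehaviorParams(startle_prob=0.0, inhibition_slope=0.0,
                           learned_fear_boost=8.0)
        diffs = []
        for seed in range(10):
            trace, _ = simulate_mouse_session(p, recall_b, seed)
            table = fk.compute_window_table({"m0": trace}, recall_b)
            diffs.append(table["difference"].mean())
        assert np.mean(diffs) > 10.0

    def test_higher_plateau_gives_stronger_inhibition(self, recall_schedule):
        """With k > 0, raising contextual freezing raises the tone-induced
        reduction — the qualitative external-inhibition relation."""
        def mean_inhibition(plateau):
            p = BehaviorParams(startle_prob=0.0, recall_plateau=plateau)
            vals = []
            for seed in range(12):
                trace, _ = simulate_mouse_session(p, recall_schedule, seed)
                table = fk.compute_window_table({"m0": trace}, recall_schedule)
                vals.append(-table["difference"].mean())
            return np.mean(vals)

        assert mean_inhibition(80.0) > mean_inhibition(35.0) + 3.0


class TestStartleInjection:
    def test_injected_startles_recovered_under_realistic_behavior(
        self, recall_schedule, fparams, sparams
    ):
        """>= 95% of injected beep-locked transients are detected even on
        top of ongoing freeze/move dynamics; extra blanking can only come
        from genuine short beep-locked movement bouts, so the corrected
        gain is never below the injected fraction."""
        p = BehaviorParams(startle_prob=0.5)
        n_injected = n_recovered = 0
        for seed in range(10):
            trace, truth = simulate_mouse_session(p, recall_schedule, seed)
            events = fk.detect_startle_events(trace, recall_schedule,
                                              fparams, sparams)
            detected = {(ev.start_sample, ev.n_samples) for ev in events}
            for inj in truth.startles:
                n_injected += 1
                if (inj.start_sample, inj.n_samples) in detected:
                    n_recovered += 1
            per_cs, _ = fk.corrected_cs_freezing(trace, recall_schedule,
                                                 fparams, sparams)
            for i, (a, b) in enumerate(recall_schedule.cs_windows()):
                i0, i1 = int(a * FS), int(b * FS)
                blanked = sum(
                    min(inj.start_sample + inj.n_samples, i1)
                    - max(inj.start_sample, i0)
                    for inj in truth.startles
                    if inj.start_sample < i1
                    and inj.start_sample + inj.n_samples > i0
                )
                injected_pct = 100.0 * blanked / (i1 - i0)
                gain = (per_cs.loc[i, "corrected_pct"]
                        - per_cs.loc[i, "raw_pct"])
                assert gain >= injected_pct - 1e-9
        assert n_injected > 50
        assert n_recovered / n_injected >= 0.95

    def test_blanked_fraction_arithmetic_on_frozen_background(self, fparams,
                                                              sparams):
        """With a continuously frozen mouse, injected startles are the only
        movement, so corrected-minus-raw CS freezing equals the injected
        blanked fraction within 1 pp."""
        sched = build_schedule("safety_short", "habituation")
        p = BehaviorParams(hab_entry_rate=5.0, hab_exit_rate=0.0,
                           startle_prob=0.5)
        n_injected = n_recovered = 0
        for seed in range(10):
            trace, truth = simulate_mouse_session(p, sched, seed)
            events = fk.detect_startle_events(trace, sched, fparams, sparams)
            detected = {(ev.start_sample, ev.n_samples) for ev in events}
            n_injected += len(truth.startles)
            n_recovered += sum(
                (inj.start_sample, inj.n_samples) in detected
                for inj in truth.startles
            )
            per_cs, _ = fk.corrected_cs_freezing(trace, sched, fparams, sparams)
            for i, (a, b) in enumerate(sched.cs_windows()):
                i0, i1 = int(a * FS), int(b * FS)
                blanked = sum(
                    inj.n_samples
                    for inj in truth.startles
                    if i0 <= inj.start_sample < i1
                )
                injected_pct = 100.0 * blanked / (i1 - i0)
                gain = (per_cs.loc[i, "corrected_pct"]
                        - per_cs.loc[i, "raw_pct"])
                assert gain == pytest.approx(injected_pct, abs=1.0)
        assert n_injected > 100
        assert n_recovered / n_injected >= 0.95

    def test_startles_do_not_change_ground_truth_state(self, recall_schedule):
        p = BehaviorParams(startle_prob=0.5)
        trace, truth = simulate_mouse_session(p, recall_schedule, 3)
        for inj in truth.startles:
            span = truth.states[inj.start_sample : inj.start_sample + inj.n_samples]
            assert span.all()  # still frozen underneath the artifact
            assert (trace.values[inj.start_sample :
                                 inj.start_sample + inj.n_samples] >= 40).all()


class TestExperiment:
    def test_us_only_short_layout(self):
        proto = build_protocol("us_only_short")
        data = simulate_experiment(proto, 5, BehaviorParams(), 1, group="US-only")
        assert len(data.traces) == 5 * 3
        assert set(data.metadata["session_kind"]) == {
            "habituation", "training", "recall"
        }
        assert len(data.metadata) == 15
        recall_traces = data.session_traces(2)
        assert len(recall_traces) == 5
        for trace in recall_traces.values():
            assert trace.n_samples == 30600

    def test_invalid_group_size_rejected(self):
        proto = build_protocol("us_only_short")
        with pytest.raises(ValueError):
            simulate_experiment(proto, 0, BehaviorParams(), 1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(startle_prob=1.5)
        with pytest.raises(ValueError):
            BehaviorParams(startle_duration_range=(0.5, 1.2))
        with pytest.raises(ValueError):
            BehaviorParams(recall_plateau=100.0)
        with pytest.raises(ValueError):
            BehaviorParams(hab_entry_rate=-0.1)
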