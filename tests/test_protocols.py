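import numpy as np
import pytest
from scipy import stats

from touchtask.core import ProtocolConfig, TouchEvent, TrialOutcome
from touchtask.devices import ScriptedTouchSource
from touchtask.protocols import (
    OutcomeHooks,
    Rect,
    RegionMap,
    TrialPlan,
    classify_touch,
    make_region_map,
    plan_sides,
    run_protocol,
    sample_iti,
    trial_block,
)
from touchtask.runner import AcceleratedClock


def down(x, y, t):
    return TouchEvent(x=x, y=y, t=t, phase="down")


class TestSampleIti:
    def test_degenerate_range_is_fixed(self):
        rng = np.random.default_rng(0)
        assert all(sample_iti((3.0, 3.0), rng) == 3.0 for _ in range(50))

    def test_same_seed_same_sequence(self):
        a = [sample_iti((4, 6), np.random.default_rng(7)) for _ in range(1)]
        draws1 = [sample_iti((4, 6), np.random.default_rng(7))]
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        s1 = [sample_iti((4, 6), r1) for _ in range(100)]
        s2 = [sample_iti((4, 6), r2) for _ in range(100)]
        assert s1 == s2

    def test_uniform_on_4_6(self):
        rng = np.random.default_rng(42)
        draws = [sample_iti((4.0, 6.0), rng) for _ in range(10_000)]
        p = stats.kstest(draws, stats.uniform(4.0, 2.0).cdf).pvalue
        assert p > 0.01
        assert min(draws) >= 4.0 and max(draws) <= 6.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_iti((6.0, 4.0), np.random.default_rng(0))


class TestPlanSides:
    def test_single_block_is_one_of_each(self):
        sides = plan_sides(2, np.random.default_rng(0))
        assert sorted(sides) == ["left", "right"]

    def test_exact_balance_at_1000(self):
        sides = plan_sides(1000, np.random.default_rng(3))
        assert sides.count("left") == 500

    def test_odd_n_differs_by_at_most_one(self):
        sides = plan_sides(1001, np.random.default_rng(3))
        assert abs(sides.count("left") - sides.count("right")) <= 1

    def test_run_length_at_most_two(self):
        sides = plan_sides(5000, np.random.default_rng(5))
        run = 1
        for a, b in zip(sides, sides[1:]):
            run = run + 1 if a == b else 1
            assert run <= 2

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            plan_sides(0, np.random.default_rng(0))


@pytest.fixture
def rmap(twoafc_cfg, screen):
    plan = TrialPlan(target_side="left", iti_duration=4.0)
    return make_region_map("twoafc", plan, twoafc_cfg, screen)


class TestClassifyTouch:
    def test_target_down_during_stimulus_is_correct(self, rmap):
        assert classify_touch(down(100, 240, 5.0), rmap, "stimulus") == "correct"

    def test_distractor_down_is_incorrect(self, rmap):
        assert classify_touch(down(700, 240, 5.0), rmap, "stimulus") == "incorrect"

    def test_any_down_during_iti_is_uncued(self, rmap):
        for x in (100, 400, 700):
            assert classify_touch(down(x, 240, 1.0), rmap, "iti") == "uncued"

    def test_dead_zone_ignored(self, rmap, screen):
        cx = screen.width_px / 2
        assert rmap.dead_zone.contains(cx, 240)
        assert classify_touch(down(cx, 240, 5.0), rmap, "stimulus") == "ignored"

    def test_reward_delay_ignored(self, rmap):
        assert classify_touch(down(100, 240, 5.0), rmap, "reward_delay") == "ignored"

    def test_only_down_events_classify(self, rmap):
        ev = TouchEvent(x=100, y=240, t=5.0, phase="move")
        assert classify_touch(ev, rmap, "stimulus") == "ignored"

    def test_out_of_bounds_rejected_with_coordinates(self, rmap, screen):
        with pytest.raises(ValueError, match="900"):
            classify_touch(down(900, 240, 5.0), rmap, "stimulus", screen)


class TestRegionMap:
    def test_dead_zone_width_matches_mm_conversion(self, rmap, screen):
        # 10 mm -> 82 px; halves may donate one spare px to the strip
        assert rmap.dead_zone.w in (82, 83)
        assert rmap.target_region.w == rmap.distractor_region.w

    def test_regions_disjoint_and_within_screen(self, rmap, screen):
        rects = [rmap.target_region, rmap.distractor_region, rmap.dead_zone]
        for r in rects:
            assert r.x >= 0 and r.x + r.w <= screen.width_px
        # pairwise disjoint on the x axis (all span full height)
        spans = sorted((r.x, r.x + r.w) for r in rects)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_single_target_covers_screen(self, phase1_cfg, screen):
        plan = TrialPlan(target_side="single", iti_duration=3.0)
        m = make_region_map("single_target", plan, phase1_cfg, screen)
        assert m.target_region.w == screen.width_px
        assert m.distractor_region is None


class TestTrialBlock:
    def run_one(self, cfg, plan, rmap, events, deadline=float("inf"), screen=None):
        return trial_block(
            plan, cfg, rmap, ScriptedTouchSource(events), OutcomeHooks(),
            AcceleratedClock(), deadline=deadline, screen=screen,
        )

    def test_silence_is_a_miss(self, twoafc_cfg, rmap):
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        rec = self.run_one(twoafc_cfg, plan, rmap, [])
        assert rec.outcome is TrialOutcome.MISS
        assert rec.response_t is None and rec.response_xy is None
        assert rec.stimulus_onset_t == 4.0
        assert rec.trial_end_t == 14.0

    def test_iti_touch_resets_then_target_touch_wins(self, twoafc_cfg, rmap):
        # uncued touch at t=1 restarts a full 4 s ITI; onset moves to 5.0
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        events = [down(400, 240, 1.0), down(100, 240, 5.5)]
        rec = self.run_one(twoafc_cfg, plan, rmap, events)
        assert rec.uncued_touch_count == 1
        assert rec.stimulus_onset_t == 5.0
        assert rec.outcome is TrialOutcome.CORRECT
        assert rec.response_t == 5.5
        assert rec.trial_end_t == pytest.approx(6.5)  # +1 s reward delay

    def test_dead_zone_touch_does_not_resolve_trial(self, twoafc_cfg, rmap):
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        events = [down(400, 240, 5.0), down(700, 240, 6.0)]
        rec = self.run_one(twoafc_cfg, plan, rmap, events)
        assert rec.outcome is TrialOutcome.INCORRECT
        assert rec.response_t == 6.0

    def test_first_qualifying_down_wins(self, twoafc_cfg, rmap):
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        events = [down(700, 240, 4.5), down(100, 240, 4.6)]
        rec = self.run_one(twoafc_cfg, plan, rmap, events)
        assert rec.outcome is TrialOutcome.INCORRECT

    def test_expiry_during_iti_truncates(self, twoafc_cfg, rmap):
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        rec = self.run_one(twoafc_cfg, plan, rmap, [], deadline=2.0)
        assert rec.outcome is TrialOutcome.TRUNCATED
        assert rec.stimulus_onset_t is None
        assert rec.trial_end_t == 2.0

    def test_expiry_during_stimulus_truncates_but_resolution_kept(self, twoafc_cfg, rmap):
        plan = TrialPlan(target_side="left", iti_duration=4.0)
        rec = self.run_one(twoafc_cfg, plan, rmap, [], deadline=9.0)
        assert rec.outcome is TrialOutcome.TRUNCATED
        resolved = self.run_one(twoafc_cfg, plan, rmap, [down(100, 240, 8.5)],
                                deadline=9.0)
        assert resolved.outcome is TrialOutcome.CORRECT
        assert resolved.trial_end_t == 9.0  # reward delay clipped at deadline


def perfect_agent(screen, seed=0, **overrides):
    from touchtask.agent import AgentParams, SyntheticAgent

    params = AgentParams(
        p_respond=1.0, accuracy=1.0, uncued_rate=0.0,
        touch_scatter_sd_mm=0.0, latency_sd=0.0, seed=seed, **overrides,
    )
    return SyntheticAgent(params, screen=screen)


class TestRunProtocol:
    def test_zero_duration_is_valid_empty_session(self, screen):
        cfg = ProtocolConfig(session_duration_s=0.0)
        rec = run_protocol("single_target", cfg, OutcomeHooks(),
                           ScriptedTouchSource([]), AcceleratedClock(),
                           screen=screen)
        assert rec.trials == [] and rec.events == []

    def test_unknown_protocol_names_registry(self, screen):
        with pytest.raises(KeyError, match="twoafc"):
            run_protocol("maze", ProtocolConfig(), OutcomeHooks(),
                         ScriptedTouchSource([]), AcceleratedClock(), screen=screen)

    def test_invalid_config_rejected(self, screen):
        cfg = ProtocolConfig(iti_range_s=(6.0, 4.0))
        with pytest.raises(ValueError, match="iti_range_s"):
            run_protocol("twoafc", cfg, OutcomeHooks(),
                         ScriptedTouchSource([]), AcceleratedClock(), screen=screen)

    def test_perfect_responder_all_correct_no_corrections(self, twoafc_cfg, screen):
        cfg = twoafc_cfg.model_copy(update={"max_trials": 20,
                                            "session_duration_s": 1e6})
        rec = run_protocol("twoafc", cfg, OutcomeHooks(), perfect_agent(screen),
                           AcceleratedClock(), screen=screen)
        assert len(rec.trials) == 20
        assert all(t.outcome is TrialOutcome.CORRECT for t in rec.trials)
        assert not any(t.is_correction for t in rec.trials)

    def test_always_wrong_responder_spawns_correction_chain(self, twoafc_cfg, screen):
        cfg = twoafc_cfg.model_copy(update={"max_trials": 15,
                                            "session_duration_s": 1e6})
        agent = perfect_agent(screen)
        agent.params = agent.params.model_copy(update={"accuracy": 0.0})
        rec = run_protocol("twoafc", cfg, OutcomeHooks(), agent,
                           AcceleratedClock(), screen=screen)
        assert all(t.outcome is TrialOutcome.INCORRECT for t in rec.trials)
        # every trial after the first is a correction repeating its side
        for prev, cur in zip(rec.trials, rec.trials[1:]):
            assert cur.is_correction
            assert cur.target_side == prev.target_side

    def test_correction_chain_survives_misses_and_ends_on_correct(self, twoafc_cfg, screen):
        from touchtask.agent import AgentParams, SyntheticAgent

        cfg = twoafc_cfg.model_copy(update={"max_trials": 120,
                                            "session_duration_s": 1e6})
        agent = SyntheticAgent(
            AgentParams(p_respond=0.6, accuracy=0.5, uncued_rate=0.05,
                        touch_scatter_sd_mm=1.0, seed=11),
            screen=screen,
        )
        rec = run_protocol("twoafc", cfg, OutcomeHooks(), agent,
                           AcceleratedClock(), screen=screen)
        assert any(t.is_correction for t in rec.trials)
        for prev, cur in zip(rec.trials, rec.trials[1:]):
            if cur.is_correction:
                assert cur.target_side == prev.target_side
                # a chain only starts after an incorrect; it persists
                # through misses and ends on correct
                assert prev.outcome is not TrialOutcome.CORRECT
            elif prev.is_correction:
                assert prev.outcome is TrialOutcome.CORRECT

    def test_gonogo_withholding_is_correct_rejection(self, phase1_cfg, screen):
        cfg = phase1_cfg.model_copy(update={"max_trials": 30,
                                            "session_duration_s": 1e6})
        rec = run_protocol("gonogo", cfg, OutcomeHooks(), perfect_agent(screen),
                           AcceleratedClock(), screen=screen)
        nogo = [t for t in rec.trials if t.go is False]
        go = [t for t in rec.trials if t.go is True]
        assert nogo and go
        for t in nogo:
            assert t.outcome is TrialOutcome.CORRECT
            assert t.response_t is None
            assert t.reward_volume_ul > 0
        for t in go:
            assert t.outcome is TrialOutcome.CORRECT
            assert t.response_t is not None

    def test_conservation_law(self, twoafc_cfg, screen):
        from touchtask.agent import AgentParams, SyntheticAgent

        cfg = twoafc_cfg.model_copy(update={"session_duration_s": 300.0})
        agent = SyntheticAgent(AgentParams(seed=3), screen=screen)
        rec = run_protocol("twoafc", cfg, OutcomeHooks(), agent,
                           AcceleratedClock(), screen=screen)
        counts = rec.outcome_counts()
        assert len(rec.trials) == sum(counts.values())

    def test_determinism_same_seed_identical_records(self, twoafc_cfg, screen):
        recs = []
        for _ in range(2):
            cfg = twoafc_cfg.model_copy(update={"session_duration_s": 200.0,
                                                "rng_seed": 9})
            recs.append(run_protocol(
                "twoafc", cfg, OutcomeHooks(), perfect_agent(screen, seed=4),
                AcceleratedClock(), screen=screen,
                session_id="fixed", start_timestamp="fixed",
            ))
        assert recs[0] == recs[1]
        assert recs[0].model_dump_json() == recs[1].model_dump_json()
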