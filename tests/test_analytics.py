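import math

import numpy as np
import pytest

from touchtask.analytics import (
    CriterionRule,
    InsufficientDataError,
    bootstrap_ci,
    dprime,
    engagement,
    learning_curve,
    mean_pairwise_distance,
    rates_from_counts,
    scatter_shift_test,
    session_metrics,
    sessions_to_criterion,
)
from touchtask.core import ScreenGeometry
from tests.conftest import make_trial, random_session
from tests.oracles import dprime_oracle


class TestDprime:
    def test_equal_rates_give_zero(self):
        for p in (0.1, 0.5, 0.9):
            assert dprime(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_separation(self):
        # H and FA one z-unit either side of chance: d' = 2/sqrt(2) = sqrt(2)
        d = dprime(0.8413, 0.1587)
        assert d == pytest.approx(dprime_oracle(0.8413, 0.1587), abs=1e-9)
        assert d == pytest.approx(math.sqrt(2.0), abs=1e-3)

    def test_antisymmetry(self):
        assert dprime(0.8, 0.3) == pytest.approx(-dprime(0.3, 0.8), abs=1e-12)

    def test_monotone_in_rates(self):
        assert dprime(0.7, 0.2) < dprime(0.8, 0.2)
        assert dprime(0.8, 0.3) < dprime(0.8, 0.2)

    @pytest.mark.parametrize("H,FA", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0),
                                      (0.5, 1.0)])
    def test_extreme_rates_direct_to_clamping(self, H, FA):
        with pytest.raises(ValueError, match="rates_from_counts"):
            dprime(H, FA)


class TestRatesFromCounts:
    def test_perfect_responder_clamped_rates(self):
        trials = (
            [make_trial(index=i + 1, outcome="correct", side="left") for i in range(10)]
            + [make_trial(index=i + 1, outcome="correct", side="right") for i in range(10)]
        )
        H, FA = rates_from_counts(trials)
        assert H == pytest.approx(10.5 / 11)
        assert FA == pytest.approx(0.5 / 11)

    def test_pure_side_bias_gives_zero_dprime(self):
        # always answers left: correct on left targets, incorrect on right
        trials = (
            [make_trial(index=i + 1, outcome="correct", side="left") for i in range(10)]
            + [make_trial(index=i + 1, outcome="incorrect", side="right") for i in range(10)]
        )
        H, FA = rates_from_counts(trials)
        assert H == FA == pytest.approx(10.5 / 11)
        assert dprime(H, FA) == pytest.approx(0.0, abs=1e-12)

    def test_corrections_and_misses_excluded(self):
        base = (
            [make_trial(index=i + 1, outcome="correct", side="left") for i in range(5)]
            + [make_trial(index=i + 1, outcome="correct", side="right") for i in range(5)]
        )
        noise = [
            make_trial(index=90, outcome="incorrect", side="left", correction=True),
            make_trial(index=91, outcome="miss", side="right", resp=None),
        ]
        assert rates_from_counts(base + noise) == rates_from_counts(base)

    def test_correction_contents_never_leak(self):
        # permuting the contents of correction trials leaves (H, FA) alone
        base = (
            [make_trial(index=i + 1, outcome="correct", side="left") for i in range(6)]
            + [make_trial(index=i + 1, outcome="incorrect", side="right") for i in range(6)]
        )
        a = base + [make_trial(index=99, outcome="correct", side="left",
                               correction=True)]
        b = base + [make_trial(index=99, outcome="incorrect", side="right",
                               correction=True)]
        assert rates_from_counts(a) == rates_from_counts(b)

    def test_all_corrections_is_insufficient(self):
        trials = [make_trial(index=i + 1, outcome="correct", side="left",
                             correction=True) for i in range(5)]
        with pytest.raises(InsufficientDataError):
            rates_from_counts(trials)


class TestEngagement:
    def test_no_misses_is_one(self):
        trials = [make_trial(index=i + 1, outcome="correct") for i in range(4)]
        assert engagement(trials) == 1.0

    def test_three_responses_one_miss(self):
        trials = [make_trial(index=i + 1, outcome="correct") for i in range(3)]
        trials.append(make_trial(index=4, outcome="miss", resp=None))
        assert engagement(trials) == pytest.approx(0.75)

    def test_all_misses_is_zero(self):
        trials = [make_trial(index=i + 1, outcome="miss", resp=None) for i in range(3)]
        assert engagement(trials) == 0.0

    def test_truncated_excluded_and_empty_errors(self):
        trials = [make_trial(index=1, outcome="truncated", resp=None)]
        with pytest.raises(InsufficientDataError):
            engagement(trials)

    def test_corrections_flag(self):
        trials = [make_trial(index=1, outcome="correct"),
                  make_trial(index=2, outcome="miss", resp=None, correction=True)]
        assert engagement(trials, include_corrections=True) == pytest.approx(0.5)
        assert engagement(trials, include_corrections=False) == 1.0


class TestSessionsToCriterion:
    def test_reward_rule_needs_consecutive_sessions(self):
        rule = CriterionRule(kind="reward_count", threshold=70, consecutive_sessions=2)
        assert sessions_to_criterion([60, 75, 80], rule) == 3
        assert sessions_to_criterion([75, 60, 75, 80], rule) == 4

    def test_dprime_rule_first_crossing(self):
        rule = CriterionRule(kind="dprime", threshold=1.5)
        assert sessions_to_criterion([0.2, 1.6], rule) == 2

    def test_never_met_and_empty(self):
        rule = CriterionRule(kind="reward_count", threshold=70, consecutive_sessions=2)
        assert sessions_to_criterion([10, 20, 30], rule) is None
        assert sessions_to_criterion([], rule) is None

    def test_threshold_is_strict(self):
        rule = CriterionRule(kind="reward_count", threshold=70)
        assert sessions_to_criterion([70, 71], rule) == 2


class TestPairwiseDistance:
    def test_two_points_five_mm_apart(self, screen):
        p1 = (0.0, 0.0)
        p2 = (5.0 * screen.px_per_mm_x, 0.0)
        assert mean_pairwise_distance([p1, p2], screen) == pytest.approx(5.0)

    def test_identical_points_zero(self, screen):
        assert mean_pairwise_distance([(10, 10)] * 5, screen) == 0.0

    def test_fewer_than_two_points_errors(self, screen):
        with pytest.raises(InsufficientDataError):
            mean_pairwise_distance([(1, 1)], screen)

    def test_anisotropic_pixels_handled_per_axis(self):
        screen = ScreenGeometry(width_px=800, height_px=480,
                                width_mm=80.0, height_mm=24.0)
        # 10 px on x = 1 mm; 20 px on y = 1 mm
        assert mean_pairwise_distance([(0, 0), (10, 0)], screen) == pytest.approx(1.0)
        assert mean_pairwise_distance([(0, 0), (0, 20)], screen) == pytest.approx(1.0)

    def test_isotropic_gaussian_matches_sigma_sqrt_pi(self, screen):
        rng = np.random.default_rng(0)
        sigma = 2.0  # mm
        pts = rng.normal(0.0, sigma, size=(2000, 2))
        px = np.column_stack([pts[:, 0] * screen.px_per_mm_x + 400,
                              pts[:, 1] * screen.px_per_mm_y + 240])
        got = mean_pairwise_distance([tuple(p) for p in px], screen)
        assert got == pytest.approx(sigma * math.sqrt(math.pi), rel=0.05)


class TestBootstrap:
    def test_constant_input_degenerate_interval(self):
        rng = np.random.default_rng(0)
        m, lo, hi = bootstrap_ci([3.0] * 10, rng=rng)
        assert m == lo == hi == 3.0

    def test_interval_brackets_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5.0, 2.0, size=200)
        m, lo, hi = bootstrap_ci(vals, rng=np.random.default_rng(2))
        assert lo <= m <= hi

    def test_deterministic_under_seed(self):
        vals = list(range(20))
        a = bootstrap_ci(vals, rng=np.random.default_rng(5))
        b = bootstrap_ci(vals, rng=np.random.default_rng(5))
        assert a == b

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_ci([])


def test_scatter_shift_test_detects_shrinkage():
    rng = np.random.default_rng(0)
    early = rng.normal(6.3, 1.0, size=400)
    late = rng.normal(2.6, 0.5, size=400)
    stat, p = scatter_shift_test(early, late)
    assert p < 1e-10
    _, p_same = scatter_shift_test(early, rng.normal(6.3, 1.0, size=400))
    assert p_same > 0.01


def test_session_metrics_and_learning_curve_run_on_any_session():
    rng = np.random.default_rng(9)
    recs = [random_session(rng) for _ in range(5)]
    table = learning_curve(recs)
    assert len(table) == 5
    for rec in recs:
        m = session_metrics(rec)
        total = m.n_correct + m.n_incorrect + m.n_miss + m.n_truncated
        assert total == len(rec.trials)
        assert m.reward_total_ul == sum(t.reward_volume_ul for t in rec.trials)
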