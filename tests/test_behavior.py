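"""Schedule math, session replay, and behavioral group statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import completed_trials_log
from fosnet.behavior import (
    Event,
    RatioSchedule,
    SessionLog,
    SessionValidationError,
    compare_groups,
    compare_survival,
    compute_break_point,
    compute_metrics,
    fr_criterion_reached,
    pr_stable,
    response_ratio,
    session_end_time,
)


class TestResponseRatio:
    @pytest.mark.parametrize(
        "m,expected", [(1, 1), (2, 2), (3, 4), (4, 6), (5, 9), (6, 12), (7, 15), (8, 20)]
    )
    def test_progressive_defaults_reproduce_canonical_sequence(self, m, expected):
        assert response_ratio(RatioSchedule.progressive(), m) == expected

    def test_rounding_not_flooring_at_m5(self):
        # 5*e^1 - 5 = 8.59...: flooring would give 8, the canonical value is 9
        assert response_ratio(RatioSchedule.progressive(), 5) == 9

    def test_fixed_schedule_is_constant(self):
        sched = RatioSchedule.fixed(3)
        assert [response_ratio(sched, m) for m in (1, 7, 57)] == [3, 3, 3]

    @pytest.mark.parametrize("m", [0, -1])
    def test_nonpositive_trial_index_rejected(self, m):
        with pytest.raises(ValueError):
            response_ratio(RatioSchedule.progressive(), m)

    @given(m=st.integers(min_value=1, max_value=60))
    @settings(deadline=None, derandomize=True)
    def test_progressive_ratio_nondecreasing_and_positive(self, m):
        sched = RatioSchedule.progressive()
        assert response_ratio(sched, m) >= 1
        assert response_ratio(sched, m + 1) >= response_ratio(sched, m)
        if m >= 2:
            assert response_ratio(sched, m + 1) > response_ratio(sched, m)


class TestBreakPoint:
    def test_five_completed_trials_break_at_fifth_ratio(self):
        assert compute_break_point(completed_trials_log(5)) == 9

    def test_no_rewards_is_zero(self):
        log = SessionLog(events=[Event(0.0, "trial_start"), Event(5.0, "correct_touch")])
        assert compute_break_point(log) == 0
        assert compute_metrics(log).no_reward

    def test_single_reward_is_first_ratio(self):
        assert compute_break_point(completed_trials_log(1)) == 1

    def test_invariant_under_trailing_non_reward_events(self):
        log = completed_trials_log(4)
        bp = compute_break_point(log)
        t = log.events[-1].time
        log.events.extend(
            [Event(t + 30, "trial_start"), Event(t + 35, "correct_touch"),
             Event(t + 40, "incorrect_touch")]
        )
        assert compute_break_point(log) == bp == 6

    def test_reward_without_enough_correct_touches_rejected(self):
        log = SessionLog(
            events=[Event(0.0, "trial_start"), Event(1.0, "correct_touch"),
                    Event(2.0, "reward_collected"), Event(35.0, "trial_start"),
                    Event(36.0, "correct_touch"), Event(37.0, "reward_collected")]
        )  # trial 2 requires 2 correct touches
        with pytest.raises(SessionValidationError):
            compute_break_point(log)

    def test_decreasing_times_rejected(self):
        log = SessionLog(events=[Event(5.0, "trial_start"), Event(1.0, "correct_touch")])
        with pytest.raises(SessionValidationError):
            log.validate()


class TestSessionEnd:
    def test_quit_window_after_last_touch(self):
        log = SessionLog(
            events=[Event(0.0, "trial_start"), Event(100.0, "correct_touch")]
        )
        assert session_end_time(log) == 400.0

    def test_continuous_touching_caps_at_max_duration(self):
        events = [Event(float(t), "incorrect_touch") for t in range(10, 3601, 10)]
        assert session_end_time(SessionLog(events=events)) == 3600.0

    def test_empty_log_times_out_after_one_quit_window(self):
        assert session_end_time(SessionLog()) == 300.0

    def test_first_long_gap_ends_session_even_with_later_touches(self):
        events = [Event(10.0, "correct_touch"), Event(1000.0, "correct_touch")]
        assert session_end_time(SessionLog(events=events)) == 310.0

    @given(gaps=st.lists(st.floats(min_value=0.1, max_value=299.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_never_exceeds_max_duration_and_caps_without_long_gaps(self, gaps):
        times = np.cumsum(gaps)
        log = SessionLog(events=[Event(float(t), "correct_touch") for t in times])
        end = session_end_time(log)
        assert end <= log.max_duration
        if times[-1] + log.quit_window >= log.max_duration:
            assert end == log.max_duration


class TestMetrics:
    def test_accuracy_is_correct_over_total_touches(self):
        log = completed_trials_log(4, incorrect_per_trial=0)
        # trials 1..4 need 1+2+4+6=13 correct; add incorrect touches by hand
        t = log.events[-1].time
        for i in range(13):  # 13 correct already present -> 13/26 would be 0.5
            log.events.append(Event(t + i + 1, "incorrect_touch"))
        m = compute_metrics(log)
        assert m.accuracy == pytest.approx(0.5)

    def test_thirty_correct_ten_incorrect_is_three_quarters(self):
        events = [Event(float(i), "correct_touch") for i in range(30)]
        events += [Event(30.0 + i, "incorrect_touch") for i in range(10)]
        assert compute_metrics(SessionLog(events=events)).accuracy == pytest.approx(0.75)

    def test_first20_window_is_half_open(self):
        events = [
            Event(1199.999, "correct_touch"),
            Event(1200.0, "correct_touch"),  # boundary: excluded
            Event(1300.0, "incorrect_touch"),
        ]
        m = compute_metrics(SessionLog(events=events))
        assert (m.correct_first20, m.incorrect_first20) == (1, 0)

    def test_all_touches_after_window_count_zero(self):
        events = [Event(1201.0 + i, "correct_touch") for i in range(5)]
        assert compute_metrics(SessionLog(events=events)).correct_first20 == 0

    def test_empty_log_yields_zeroed_metrics_with_missing_accuracy(self):
        m = compute_metrics(SessionLog())
        assert m.break_point == 0 and m.n_rewards == 0
        assert math.isnan(m.accuracy) and math.isnan(m.first_touch_latency_mean)

    def test_first_touch_latency_averages_over_touched_trials(self):
        events = [
            Event(0.0, "trial_start"), Event(4.0, "incorrect_touch"),
            Event(6.0, "correct_touch"), Event(8.0, "reward_collected"),
            Event(40.0, "trial_start"), Event(48.0, "correct_touch"),
        ]
        m = compute_metrics(SessionLog(events=events))
        assert m.first_touch_latency_mean == pytest.approx((4.0 + 8.0) / 2)


class TestCriteria:
    @pytest.mark.parametrize(
        "stage,rewards,expected",
        [
            ("FR1", [12, 55], True),
            ("FR1", [49], False),
            ("FR2", [50], True),
            ("FR3", [60, 49], False),
            ("FR3", [50, 50], True),
            ("FR3", [55], False),  # one day is insufficient evidence
        ],
    )
    def test_fixed_ratio_advance_rule(self, stage, rewards, expected):
        assert fr_criterion_reached(rewards, stage) is expected

    def test_fr_rejects_empty_and_unknown_stage(self):
        with pytest.raises(ValueError):
            fr_criterion_reached([], "FR1")
        with pytest.raises(ValueError):
            fr_criterion_reached([50], "FR9")

    @pytest.mark.parametrize(
        "rewards,stable,mean",
        [
            ([30, 30, 30], True, 30.0),
            ([30, 40, 20], False, None),  # 40 is +33% of the 3-day mean
            ([100, 95, 105], True, 100.0),  # max deviation 5%
            ([10, 10, 30, 30, 30], True, 30.0),  # only the last 3 days matter
        ],
    )
    def test_pr_stabilization_rule(self, rewards, stable, mean):
        got_stable, got_mean = pr_stable(rewards)
        assert got_stable is stable
        if mean is None:
            assert got_mean is None
        else:
            assert got_mean == pytest.approx(mean)

    def test_pr_stable_needs_three_days(self):
        with pytest.raises(ValueError):
            pr_stable([30, 30])


class TestGroupComparisons:
    def test_identical_groups_t_zero_p_one(self):
        assert compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_textbook_pooled_t(self):
        # hand evaluation: t = (2-5)/sqrt(1*(1/3+1/3)) = -3.674
        t, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=0.005)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-10)

    def test_zero_variance_unequal_means_signalled(self):
        with pytest.raises(ValueError):
            compare_groups([2.0, 2.0], [3.0, 3.0])

    def test_zero_variance_equal_means_is_null(self):
        assert compare_groups([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_welch_option_differs_under_unequal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [0.0, 10.0, -10.0, 20.0, -20.0, 30.0]
        t_student, _ = compare_groups(a, b)
        t_welch, _ = compare_groups(a, b, welch=True)
        assert t_student != t_welch

    def test_t_test_type_I_error_near_nominal(self):
        rng = np.random.default_rng(20260928)
        n_sim, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            rejections += compare_groups(a, b)[1] < alpha
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 3 * se


class TestLogRank:
    def test_identical_duration_lists_are_null(self):
        res = compare_survival([100, 200, 300], [False] * 3, [100, 200, 300], [False] * 3)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_match_hand_computed_table(self):
        # single event time t=100: O_A=10, E_A=10*10/20=5,
        # Var=10*(1/2)*(1/2)*(10/19); chi2 = 25/(25/19) = 19
        res = compare_survival([100] * 10, [False] * 10, [3600] * 10, [True] * 10)
        assert res.chi_square == pytest.approx(19.0, abs=0.5)
        assert res.p_value < 1e-4

    def test_all_censored_both_groups_signalled(self):
        with pytest.raises(ValueError):
            compare_survival([3600] * 3, [True] * 3, [3600] * 3, [True] * 3)

    def test_log_rank_type_I_error_near_nominal(self):
        rng = np.random.default_rng(42)
        n_sim, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.exponential(1000.0, size=10)
            b = rng.exponential(1000.0, size=10)
            res = compare_survival(a, [False] * 10, b, [False] * 10)
            rejections += res.p_value < alpha
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 3 * se


class TestSessionCsv:
    def test_round_trip(self, tmp_path):
        log = completed_trials_log(3, incorrect_per_trial=1)
        path = tmp_path / "session.csv"
        log.to_csv(path)
        back = SessionLog.read_csv(path)
        assert [(e.time, e.kind) for e in back.events] == [
            (round(e.time, 3), e.kind) for e in log.events
        ]
        back.validate()

    def test_unknown_event_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,event\n1.0,panel_lick\n")
        with pytest.raises(SessionValidationError, match="panel_lick"):
            SessionLog.read_csv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,e\n1.0,correct_touch\n")
        with pytest.raises(SessionValidationError):
            SessionLog.read_csv(path)
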