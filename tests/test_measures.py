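import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nntbench import (
    IntervalEstimate,
    UndefinedRatioError,
    absolute_risk_reduction,
    from_counts,
    from_rates,
    nnh,
    nnt,
    nnt_from_baseline,
    nnt_interval,
    odds_ratio,
    relative_risk,
    relative_risk_reduction,
)

# strategy: tables with both arms non-empty, moderate size so the
# brute-force NNT oracle loop stays short
cells = st.integers(min_value=0, max_value=40)
tables = st.tuples(cells, cells, cells, cells).filter(
    lambda t: t[0] + t[1] >= 1 and t[2] + t[3] >= 1
).map(lambda t: from_counts(*t))


class TestRatioMeasures:
    def test_worked_example_rr(self, worked_example_table):
        rr = relative_risk(worked_example_table)
        assert rr.point == Fraction(25, 35)
        assert round(float(rr.point), 2) == 0.71

    def test_worked_example_rrr(self, worked_example_table):
        rrr = relative_risk_reduction(worked_example_table)
        assert round(float(rrr.point), 2) == 0.29

    def test_identical_arms_are_null(self):
        t = from_counts(30, 70, 30, 70)
        assert relative_risk(t).point == 1
        assert relative_risk_reduction(t).point == 0
        assert odds_ratio(t).point == 1

    def test_rr_log_normal_ci_matches_hand_formula(self):
        rr = relative_risk(from_counts(10, 90, 20, 80))
        assert rr.point == Fraction(1, 2)
        assert rr.lower == pytest.approx(0.2466408016829456, rel=1e-12)
        assert rr.upper == pytest.approx(1.0136197997011570, rel=1e-12)

    def test_rr_ci_matches_statsmodels(self):
        import statsmodels.api as sm

        t = from_counts(25, 75, 35, 65)
        ours = relative_risk(t)
        ref = sm.stats.Table2x2(np.array([[25, 75], [35, 65]]))
        assert float(ours.point) == pytest.approx(ref.riskratio, rel=1e-12)
        assert (ours.lower, ours.upper) == pytest.approx(ref.riskratio_confint(), rel=1e-9)

    def test_or_point_and_ci_match_statsmodels(self):
        import statsmodels.api as sm

        t = from_counts(25, 75, 35, 65)
        ours = odds_ratio(t)
        assert float(ours.point) == pytest.approx(25 * 65 / (75 * 35), rel=1e-12)
        ref = sm.stats.Table2x2(np.array([[25, 75], [35, 65]]))
        assert (ours.lower, ours.upper) == pytest.approx(ref.oddsratio_confint(), rel=1e-9)

    def test_zero_control_events_raise(self):
        with pytest.raises(UndefinedRatioError):
            relative_risk(from_counts(5, 5, 0, 10))

    def test_zero_cell_or_raises_without_continuity(self):
        with pytest.raises(UndefinedRatioError):
            odds_ratio(from_counts(5, 0, 5, 5))

    def test_continuity_adjusts_ci_only(self):
        # a=0: point stays exactly 0, CI comes from adjusted cells
        rr = relative_risk(from_counts(0, 10, 5, 5), continuity=True)
        assert rr.point == 0
        assert rr.lower == 0  # clamped to the unadjusted point
        assert rr.upper is not None and rr.upper > 0

    def test_rrr_is_one_minus_rr_with_swapped_limits(self):
        t = from_counts(10, 90, 20, 80)
        rr, rrr = relative_risk(t), relative_risk_reduction(t)
        assert rrr.point == 1 - rr.point
        assert rrr.lower == pytest.approx(1 - rr.upper)
        assert rrr.upper == pytest.approx(1 - rr.lower)

    @given(tables)
    def test_or_below_rr_below_one_on_protective_region(self, t):
        # whenever 0 < p_exp < p_ctrl < 1 the odds ratio exaggerates the
        # protection relative to the risk ratio
        if not (0 < t.exp_rate < t.ctrl_rate < 1):
            return
        rr = relative_risk(t).point
        orr = odds_ratio(t).point
        assert orr < rr < 1


class TestAbsoluteRiskReduction:
    def test_worked_example_point(self, worked_example_table):
        arr = absolute_risk_reduction(worked_example_table)
        assert arr.point == Fraction(1, 10)

    def test_wald_ci_matches_hand_formula(self, worked_example_table):
        arr = absolute_risk_reduction(worked_example_table)
        assert arr.lower == pytest.approx(-0.026261847388198062, rel=1e-12)
        assert arr.upper == pytest.approx(0.22626184738819807, rel=1e-12)
        assert arr.lower < 0.10 < arr.upper

    def test_identical_arms_ci_symmetric_about_zero(self):
        arr = absolute_risk_reduction(from_counts(30, 70, 30, 70))
        assert arr.point == 0
        assert arr.lower == pytest.approx(-arr.upper)

    def test_newcombe_matches_statsmodels(self, worked_example_table):
        from statsmodels.stats.proportion import confint_proportions_2indep

        arr = absolute_risk_reduction(worked_example_table, method="newcombe")
        ref = confint_proportions_2indep(35, 100, 25, 100,
                                         method="newcomb", compare="diff")
        assert (arr.lower, arr.upper) == pytest.approx(tuple(map(float, ref)))

    def test_unknown_method_rejected(self, worked_example_table):
        with pytest.raises(ValueError, match="newcombe"):
            absolute_risk_reduction(worked_example_table, method="exact")


class TestNNT:
    @pytest.mark.parametrize(
        "arr, value",
        [(0.10, 10), (0.01, 100), (0.058, 18), (Fraction(58, 1000), 18)],
    )
    def test_point_values(self, arr, value):
        res = nnt(arr)
        assert res.status == "finite"
        assert res.value == value

    def test_negative_difference_is_not_applicable(self):
        res = nnt(-0.004)
        assert res.status == "not_applicable"
        assert res.value is None

    def test_zero_difference_is_infinite(self):
        res = nnt(0)
        assert res.status == "infinite"
        assert res.raw_reciprocal == math.inf

    def test_exact_integer_reciprocal_stays(self):
        # 1/0.10 must give 10 even through float representation
        assert nnt(0.1).value == 10
        assert nnt(Fraction(1, 10)).value == 10

    def test_nearest_rounding_mode(self):
        # 1/0.037 = 27.03 -> 27 nearest, 28 ceiling
        assert nnt(Fraction(37, 1000)).value == 28
        assert nnt(Fraction(37, 1000), rounding="nearest").value == 27

    def test_raw_reciprocal_reported(self):
        res = nnt(Fraction(26, 1000))
        assert res.value == 39
        assert res.raw_reciprocal == pytest.approx(38.4615, abs=1e-3)

    @given(tables)
    def test_brute_force_oracle_equivalence(self, t):
        # NNT is the smallest k such that k * ARR >= 1, by exhaustive search
        arr = t.ctrl_rate - t.exp_rate
        if arr <= 0:
            return
        res = nnt(arr)
        k = next(k for k in range(1, 10**6) if k * arr >= 1)
        assert res.value == k

    @given(tables)
    def test_swapping_arms_flips_status(self, t):
        arr = t.ctrl_rate - t.exp_rate
        if arr == 0:
            return
        direct = nnt(arr)
        swapped = nnt(t.swapped().ctrl_rate - t.swapped().exp_rate)
        assert {direct.status, swapped.status} == {"finite", "not_applicable"}

    @given(st.fractions(min_value=Fraction(1, 1000), max_value=1),
           st.fractions(min_value=0, max_value=Fraction(999, 1000)))
    def test_monotone_nonincreasing_in_arr(self, arr, bump):
        bigger = arr + bump * (1 - arr)
        assert nnt(bigger).value <= nnt(arr).value


class TestNNTInterval:
    def test_reciprocal_ci_example(self):
        est = IntervalEstimate(Fraction(1, 10), 0.08, 0.12)
        res = nnt(est)
        assert res.value == 10
        assert (res.interval.lower, res.interval.upper) == (9, 13)
        assert not res.interval.spans_zero

    def test_spans_zero_runs_to_infinity(self):
        iv = nnt_interval(IntervalEstimate(0.02, -0.02, 0.06))
        assert iv.lower == 17
        assert iv.upper == math.inf
        assert iv.spans_zero

    def test_degenerate_interval(self):
        iv = nnt_interval(IntervalEstimate(0.1, 0.1, 0.1))
        assert (iv.lower, iv.upper) == (10, 10)

    def test_both_limits_negative_reports_harm_side(self):
        iv = nnt_interval(IntervalEstimate(-0.1, -0.12, -0.08))
        assert iv.side == "harm"
        assert (iv.lower, iv.upper) == (9, 13)
        assert not iv.spans_zero

    @given(tables)
    def test_limits_bracket_point_when_ci_excludes_zero(self, t):
        arr = absolute_risk_reduction(t)
        if arr.lower is None or arr.lower <= 0 or arr.point <= 0:
            return
        res = nnt(arr)
        assert res.interval.lower <= res.value <= res.interval.upper


class TestNNH:
    @pytest.mark.parametrize(
        "exp_rate, ctrl_rate, n, m, value",
        [
            ("5.5e-2", "3.4e-2", 1020, 1013, 48),   # hypocalcemia, breast
            (0.128, 0.058, 943, 918, 15),           # hypocalcemia, prostate
        ],
    )
    def test_excess_harm_gives_finite_nnh(self, exp_rate, ctrl_rate, n, m, value):
        res = nnh(from_rates(exp_rate, ctrl_rate, n, m))
        assert res.direction == "harm"
        assert res.status == "finite"
        assert res.value == value

    def test_safer_experimental_arm_is_not_applicable(self):
        res = nnh(from_rates(0.049, 0.085, 1020, 1013))
        assert res.status == "not_applicable"


class TestNNTFromBaseline:
    def test_trial_own_baseline_recovers_trial_nnt(self, worked_example_table):
        t = worked_example_table
        rrr = relative_risk_reduction(t).point
        direct = nnt(t.ctrl_rate - t.exp_rate)
        assert nnt_from_baseline(rrr, t.ctrl_rate).value == direct.value == 10

    def test_low_baseline_inflates_nnt(self):
        assert nnt_from_baseline(0.29, 0.05).value == 69

    def test_certain_event_fully_prevented(self):
        assert nnt_from_baseline(1.0, 1.0).value == 1

    def test_zero_baseline_is_infinite(self):
        assert nnt_from_baseline(0.5, 0).status == "infinite"

    @given(tables)
    def test_identity_at_trial_baseline_for_all_tables(self, t):
        arr = t.ctrl_rate - t.exp_rate
        if arr <= 0 or t.ctrl_rate == 0:
            return
        rrr = Fraction(1) - t.exp_rate / t.ctrl_rate
        assert nnt_from_baseline(rrr, t.ctrl_rate).value == nnt(arr).value


class TestIntervalEstimate:
    def test_limits_must_bracket_point(self):
        with pytest.raises(ValueError):
            IntervalEstimate(0.5, 0.6, 0.7)

    def test_level_must_be_probability(self):
        with pytest.raises(ValueError):
            IntervalEstimate(0.5, level=1.5)
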