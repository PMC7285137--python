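"""Accuracy statistics: bias, MAPE, CCF, exact binomial CIs, Bland-Altman,
median-difference inference, report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pedree import (
    PairedSeries,
    StudyConfig,
    ValidationError,
    absolute_bias,
    bland_altman,
    build_report,
    ccf,
    clopper_pearson,
    evaluate_all,
    mape,
    median_iqr,
    paired_median_difference,
    percent_bias,
    round_half_up,
)


def pair(mree, eree):
    return PairedSeries(mree=np.asarray(mree, float), eree=np.asarray(eree, float))


class TestElementwise:
    def test_absolute_bias(self):
        assert absolute_bias(pair([1000], [1100])).tolist() == [100.0]
        assert absolute_bias(pair([1500, 900], [1500, 900])).tolist() == [0.0, 0.0]

    def test_percent_bias_signs(self):
        p = pair([1000, 1000], [1100, 900])
        np.testing.assert_allclose(percent_bias(p), [10.0, -10.0])

    @given(st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_percent_bias_scale_invariant(self, c):
        a = pair([1000, 1400, 2000], [1100, 1300, 2300])
        b = pair(a.mree * c, a.eree * c)
        np.testing.assert_allclose(percent_bias(a), percent_bias(b), rtol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pair([1000, 1100], [1000])

    def test_random_vectors_match_independent_arithmetic(self, rng):
        m = rng.uniform(1000, 2500, 200)
        e = rng.uniform(1000, 2500, 200)
        p = pair(m, e)
        # second, index-by-index implementation
        np.testing.assert_allclose(absolute_bias(p), [e[i] - m[i] for i in range(200)])
        np.testing.assert_allclose(percent_bias(p), [(e[i] - m[i]) / m[i] * 100 for i in range(200)])


class TestMape:
    def test_perfect_agreement_is_zero(self):
        assert mape(pair([1000, 1500], [1000, 1500])) == 0.0

    def test_uniform_ten_percent_overestimate(self):
        m = np.array([1000.0, 1500.0, 2000.0])
        assert mape(pair(m, 1.1 * m)) == pytest.approx(10.0, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_mape_bounds_mean_percent_bias(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(1000, 2500, 50)
        e = m * rng.uniform(0.7, 1.3, 50)
        p = pair(m, e)
        pb = percent_bias(p)
        assert mape(p) >= abs(pb.mean()) - 1e-12
        assert mape(p) == pytest.approx(np.mean(np.abs(pb)), rel=1e-12)


class TestCCF:
    def test_boundary_inclusive(self):
        # -10.0% counts as correct; +20% does not
        count, frac = ccf(pair([1000, 1000, 1000], [1050, 1200, 900]))
        assert count == 2 and frac == pytest.approx(2 / 3)

    def test_all_equal_gives_one(self):
        assert ccf(pair([1000] * 4, [1000] * 4)) == (4, 1.0)

    def test_published_count_reproduces_fraction(self):
        # 192 of 273 correctly classified -> 70.3%
        assert round_half_up(100 * 192 / 273, 1) == 70.3

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(1000, 2500, 40)
        e = m * rng.uniform(0.7, 1.3, 40)
        p = pair(m, e)
        counts = [ccf(p, t)[0] for t in (5, 10, 15, 20, 30)]
        assert counts == sorted(counts)


class TestClopperPearson:
    def test_degenerate_bounds(self):
        low, _ = clopper_pearson(0, 10)
        _, high = clopper_pearson(10, 10)
        assert low == 0.0 and high == 1.0

    def test_interval_contains_point_estimate(self):
        for count, n in [(1, 10), (50, 116), (192, 273), (800, 1194)]:
            low, high = clopper_pearson(count, n)
            assert low <= count / n <= high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            clopper_pearson(5, 0)
        with pytest.raises(ValidationError):
            clopper_pearson(11, 10)

    def test_equals_binomial_tail_inversion_small_n(self):
        # independent oracle: invert the binomial tail by bisection
        def tail_invert(count, n, level=0.95):
            alpha = 1 - level

            def solve(f, lo, hi):
                for _ in range(200):
                    mid = (lo + hi) / 2
                    if f(mid) > 0:
                        lo = mid
                    else:
                        hi = mid
                return (lo + hi) / 2

            # both functions arranged to be decreasing in p for the solver
            low = 0.0 if count == 0 else solve(
                lambda p: alpha / 2 - stats.binom.sf(count - 1, n, p), 0.0, 1.0)
            high = 1.0 if count == n else solve(
                lambda p: stats.binom.cdf(count, n, p) - alpha / 2, 0.0, 1.0)
            return low, high

        for n in range(1, 31):
            for count in range(n + 1):
                got = clopper_pearson(count, n)
                want = tail_invert(count, n)
                assert got[0] == pytest.approx(want[0], abs=1e-9)
                assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_exact_coverage_is_conservative(self):
        # coverage computed exactly by summing the binomial pmf over the
        # counts whose interval contains p; always >= the nominal level
        for p in (0.1, 0.5, 0.65, 0.9):
            for n in (20, 116, 273):
                ks = np.arange(n + 1)
                covered = [
                    lo <= p <= hi
                    for lo, hi in (clopper_pearson(int(k), n) for k in ks)
                ]
                coverage = float(stats.binom.pmf(ks, n, p)[covered].sum())
                assert coverage >= 0.95


class TestMedianIQR:
    def test_three_values_linear_interpolation(self):
        assert median_iqr([1, 2, 3]) == (2.0, 1.5, 2.5)

    def test_constant_vector(self):
        assert median_iqr([7.0] * 5) == (7.0, 7.0, 7.0)

    def test_permutation_invariant(self, rng):
        a = rng.uniform(0, 1, 31)
        b = rng.permutation(a)
        assert median_iqr(a) == median_iqr(b)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            median_iqr([])


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman(pair([1000, 1500, 2000], [1000, 1500, 2000]))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.pct_differences, 0.0)
        assert not res.proportional_bias_flag

    def test_multiplicative_bias_is_not_proportional_on_percent_scale(self):
        m = np.array([1000.0, 1400.0, 1800.0, 2200.0])
        res = bland_altman(pair(m, 1.1 * m))
        np.testing.assert_allclose(res.pct_differences, 10.0)
        assert res.slope == pytest.approx(0.0, abs=1e-10)

    def test_constant_additive_offset_gives_negative_slope(self, rng):
        m = rng.uniform(1000, 2500, 100)
        res = bland_altman(pair(m, m + 200.0))
        assert res.slope < 0
        assert res.proportional_bias_flag   # clear proportional bias

    def test_slope_matches_closed_form_ols(self):
        m = np.array([1000.0, 1500.0, 2500.0])
        e = m + 200.0
        res = bland_altman(pair(m, e))
        avg = (e + m) / 2
        pct = 100 * (e - m) / m
        want = np.polyfit(avg, pct, 1)[0]
        assert res.slope == pytest.approx(want, rel=1e-9)

    def test_needs_three_pairs(self):
        with pytest.raises(ValidationError):
            bland_altman(pair([1000, 1100], [1000, 1100]))


class TestPairedMedianDifference:
    def test_exact_shift_recovered(self, rng):
        m = rng.uniform(1000, 2000, 60)
        res = paired_median_difference(pair(m, m + 100.0))
        assert res.median_diff == pytest.approx(100.0, rel=1e-9)
        assert res.p_value < 0.05

    def test_degenerate_all_zero(self):
        m = np.linspace(1000, 2000, 12)
        res = paired_median_difference(pair(m, m))
        assert res.median_diff == 0.0
        assert res.p_value == 1.0 and res.degenerate

    def test_null_rejection_rate_near_alpha(self):
        # paired exchangeable noise: the test should reject ~5% of the time
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 400
        for i in range(reps):
            m = rng.uniform(1200, 2200, 80)
            e = m * np.exp(rng.normal(0, 0.08, 80))   # symmetric on log scale
            res = paired_median_difference(pair(m, e), n_boot=500, seed=i)
            rejections += res.p_value < 0.05
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07

    def test_quantreg_route_detects_clear_shift(self, rng):
        m = rng.uniform(1200, 2200, 120)
        res = paired_median_difference(pair(m, m * 1.15), method="quantreg")
        assert res.method == "quantreg_robust"
        assert res.median_diff > 0 and res.p_value < 0.001


class TestBuildReport:
    def test_fifty_rows_and_ccf_additivity(self, default_cohort, config):
        table = evaluate_all(default_cohort)
        reports = build_report(table, default_cohort, config)
        assert len(reports) == 50   # 10 equations x (4 strata + all children)
        for eq in table.columns:
            rows = [r for r in reports if r.equation_id == eq]
            strata_counts = sum(r.ccf_count for r in rows if r.group != "all children")
            overall = next(r for r in rows if r.group == "all children")
            assert strata_counts == overall.ccf_count
            assert overall.n == len(default_cohort)

    def test_missing_mree_raises_stage_error(self, tiny_subjects):
        from pedree import StageError, WeightStatus
        for s in tiny_subjects:
            s.weight_status = WeightStatus.NORMAL
        tiny_subjects[1].mree_kcal_d = None
        table = evaluate_all(tiny_subjects)
        with pytest.raises(StageError, match="b"):
            build_report(table, tiny_subjects, StudyConfig())


class TestRounding:
    @pytest.mark.parametrize("x,d,want", [
        (0.625, 2, 0.63),    # half-up, not banker's
        (70.25, 1, 70.3),
        (-1.5, 0, -2.0),
        (63.232, 0, 63.0),
    ])
    def test_half_up(self, x, d, want):
        assert round_half_up(x, d) == want
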