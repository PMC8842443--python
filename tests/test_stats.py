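"""Cohort statistics: designation, stall rates, Bland–Altman, moments,
comparisons, regressions, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import capillux as cx


class TestDesignation:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([180, 190, 200], False),
            ([240, 260, 270], True),
            ([300, 200, 300, 200], False),
            ([200, 251, 252], True),
            ([250, 250, 250], False),  # strict inequality
        ],
    )
    def test_consecutive_rule(self, series, expected):
        assert cx.designate_hyperglycemic(series) is expected

    def test_requires_two_readings(self):
        with pytest.raises(ValueError):
            cx.designate_hyperglycemic([400.0])


class TestStallRate:
    def test_study_counts(self):
        eu = np.zeros(589, dtype=bool)
        eu[:9] = True
        assert cx.stall_rate(eu) == 1.52
        hy = np.zeros(440, dtype=bool)
        hy[:7] = True
        assert cx.stall_rate(hy) == 1.59

    def test_zero_stalls(self):
        assert cx.stall_rate(np.zeros(100, dtype=bool)) == 0.0

    def test_rate_times_n_recovers_count(self):
        flags = np.zeros(250, dtype=bool)
        flags[:13] = True
        assert round(100 * 13 / 250, 2) == cx.stall_rate(flags)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cx.stall_rate([])


class TestToleranceFactor:
    def test_exact_factor_by_monte_carlo_coverage(self):
        # k is calibrated so that xbar +/- k s covers >= 95% of the normal
        # population in exactly 95% of samples
        n = 10
        k = cx.tolerance_factor(n, 0.95, 0.95)
        rng = np.random.default_rng(1)
        xs = rng.standard_normal((40000, n))
        xbar, s = xs.mean(1), xs.std(1, ddof=1)
        cov = sps.norm.cdf(xbar + k * s) - sps.norm.cdf(xbar - k * s)
        assert (cov >= 0.95).mean() == pytest.approx(0.95, abs=0.01)

    def test_howe_approximation_close_to_exact(self):
        k_exact = cx.tolerance_factor(38, 0.95, 0.95)
        k_howe = cx.tolerance_factor(38, 0.95, 0.95, method="howe")
        assert k_howe == pytest.approx(k_exact, rel=0.02)

    def test_factor_decreases_with_n(self):
        ks = [cx.tolerance_factor(n, 0.95, 0.95, method="howe") for n in (5, 10, 40)]
        assert ks[0] > ks[1] > ks[2] > 1.96


class TestBlandAltman:
    def test_identical_graders_zero_bias_zero_width(self):
        table = np.tile(np.array([[100.0], [50.0], [210.0]]), (1, 5))
        res = cx.bland_altman(table, method="howe")
        for r in res.values():
            assert r.bias == 0.0
            assert r.loa_low == r.loa_high == 0.0
            assert r.degenerate

    def test_constant_offset_grader_bias(self):
        # one grader = others + c: its bias is c * (1 - 1/n_graders)
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 200, size=20)
        c = 6.0
        table = np.column_stack([base, base, base, base + c])
        res = cx.bland_altman(table, method="howe")
        assert res["grader4"].bias == pytest.approx(c * (1 - 1 / 4))
        assert res["grader1"].bias == pytest.approx(-c / 4)

    def test_biases_sum_to_zero(self):
        rng = np.random.default_rng(3)
        table = rng.uniform(0, 300, size=(38, 5))
        res = cx.bland_altman(table, method="howe")
        graders = [k for k in res if k != "pooled"]
        assert sum(res[g].bias for g in graders) == pytest.approx(0.0, abs=1e-9)

    def test_loa_halfwidth_matches_known_grader_noise(self):
        # 5 graders x 38 capillaries with grader noise SD 5 cells/s:
        # differences to the grader mean have SD 5*sqrt(1 - 1/5)
        sd_noise, n_graders = 5.0, 5
        target = 1.96 * sd_noise * np.sqrt(1 - 1 / n_graders)
        halfwidths = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            truth = rng.uniform(20, 300, size=38)
            table = truth[:, None] + rng.normal(0, sd_noise, size=(38, n_graders))
            res = cx.bland_altman(table, method="howe")["pooled"]
            halfwidths.append((res.loa_high - res.loa_low) / 2)
        assert abs(np.mean(halfwidths) - target) / target < 0.15

    def test_ci_contains_point_estimates(self):
        rng = np.random.default_rng(4)
        table = rng.uniform(0, 300, size=(12, 3))
        res = cx.bland_altman(table)["pooled"]
        assert res.ci_bias[0] <= res.bias <= res.ci_bias[1]
        assert res.ci_loa_high[0] <= res.loa_high <= res.ci_loa_high[1]
        assert res.ci_loa_low[0] <= res.loa_low <= res.ci_loa_low[1]

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            cx.bland_altman(np.ones((2, 5)))
        with pytest.raises(ValueError):
            cx.bland_altman(np.ones((10, 1)))


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        assert cx.adjusted_skew([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_and_scipy(self):
        x = np.array([0.0, 0.0, 1.0])
        n = 3
        s = x.std(ddof=1)
        m3 = np.mean((x - x.mean()) ** 3)
        direct = n * n / ((n - 1) * (n - 2)) * m3 / s**3
        assert cx.adjusted_skew(x) == pytest.approx(direct)
        assert cx.adjusted_skew(x) == pytest.approx(sps.skew(x, bias=False))

    def test_kurtosis_matches_scipy_bias_corrected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=50)
        assert cx.excess_kurtosis(x) == pytest.approx(
            sps.kurtosis(x, bias=False), rel=1e-12
        )

    def test_gaussian_large_sample_limits(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(10_000)
        assert abs(cx.adjusted_skew(x)) < 0.05
        assert abs(cx.excess_kurtosis(x)) < 0.1

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cx.adjusted_skew([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            cx.excess_kurtosis([2.0, 2.0, 2.0, 2.0])


class TestGroupCompare:
    def test_identical_samples_p_one(self):
        res = cx.group_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p == 1.0 and res.t == 0.0

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.1, 50)
        b = rng.normal(10, 0.1, 50)
        assert cx.group_compare(a, b).p < 1e-6

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        assert abs(cx.group_compare(a, b).t) == pytest.approx(
            abs(cx.group_compare(b, a).t)
        )

    def test_matches_pooled_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1.5, 18)
        res = cx.group_compare(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(float(t)) and res.p == pytest.approx(float(p))

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            cx.group_compare([1.0, 1.0], [2.0, 2.0])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = cx.regression_r2_slope(x, 2 * x)
        assert res.slope == pytest.approx(2.0) and res.r2 == pytest.approx(1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(10)
        res = cx.regression_r2_slope(rng.uniform(size=10_000), rng.uniform(size=10_000))
        assert res.r2 < 0.01

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            cx.regression_r2_slope(np.ones(5), np.arange(5.0))

    def test_recovers_builtin_flux_diameter_slope(self):
        # the cohort generator couples flux to diameter at 45 cells/s/um with
        # enough residual spread to keep the correlation weak (R^2 ~ 0.1-0.2)
        slopes, r2s = [], []
        for seed in range(8):
            ves = cx.simulate_cohort(cx.CohortSimParams(seed=seed)).vessels
            ves = ves[~ves.stalled]
            res = cx.regression_r2_slope(ves.diameter_um, ves.flux_cells_s)
            slopes.append(res.slope)
            r2s.append(res.r2)
        assert abs(np.mean(slopes) - 45.0) / 45.0 < 0.2
        assert 0.03 < np.mean(r2s) < 0.35


class TestAgeGroupsAndSummary:
    @pytest.mark.parametrize("week,expected", [(5, "young"), (12, "young"), (13, "mature"), (18, "mature")])
    def test_age_split(self, week, expected):
        assert cx.age_group(week) == expected

    def test_pre_study_week_rejected(self):
        with pytest.raises(ValueError):
            cx.age_group(4)

    def test_single_observation_sd_zero(self):
        df = pd.DataFrame(
            {"group": ["a"], "week": [5], "flux_cells_s": [100.0]}
        )
        out = cx.weekly_summary(df, "flux_cells_s")
        assert out.sd.iloc[0] == 0.0 and out.n.iloc[0] == 1

    def test_disjoint_weeks_give_disjoint_series(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 2 + ["b"] * 2,
                "week": [5, 6, 9, 10],
                "flux_cells_s": [1.0, 2.0, 3.0, 4.0],
            }
        )
        out = cx.weekly_summary(df, "flux_cells_s")
        assert set(out[out.group == "a"].week) == {5, 6}
        assert set(out[out.group == "b"].week) == {9, 10}

    def test_row_order_invariance(self):
        table = cx.simulate_cohort(cx.CohortSimParams(seed=12)).vessels
        shuffled = table.sample(frac=1.0, random_state=0)
        a = cx.weekly_summary(table, "flux_cells_s")
        b = cx.weekly_summary(shuffled, "flux_cells_s")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            cx.weekly_summary(pd.DataFrame({"group": ["a"], "week": [5]}), "nope")

    def test_no_week_trend_in_default_flux(self):
        # the generator has no built-in week trend: slope CI covers zero in
        # most seeded cohorts
        covered = 0
        for seed in range(10):
            table = cx.simulate_cohort(cx.CohortSimParams(seed=seed)).vessels
            week = table.week.to_numpy(float)
            flux = table.flux_cells_s.to_numpy(float)
            res = sps.linregress(week, flux)
            lo = res.slope - 1.96 * res.stderr
            hi = res.slope + 1.96 * res.stderr
            covered += lo <= 0.0 <= hi
        assert covered >= 8
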