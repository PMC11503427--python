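import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thyrosens.stats import (
    bootstrap_correlation,
    chi_square_independence,
    oneway_anova,
    ols_fit,
    pearson_r,
    stratified_correlation,
    tukey_kramer,
    twoway_anova,
)

from conftest import brute_chi2, brute_f_oneway, brute_pearson, build_cohort


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_r([1, 2, 3, 5], [3, 5, 7, 11])
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)
        assert res.n == 4

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(size=(2, 30))
        base = pearson_r(x, y).r
        assert pearson_r(2 * x + 7, y).r == pytest.approx(base)
        assert pearson_r(-3 * x, y).r == pytest.approx(-base)

    def test_pairwise_deletion(self):
        res = pearson_r([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="pairs"):
            pearson_r([1, 2], [3, 4])

    def test_constant_variable_named_in_error(self):
        with pytest.raises(ValueError, match="y"):
            pearson_r([1, 2, 3], [5, 5, 5])


class TestBootstrap:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        res = bootstrap_correlation(x, x, b=200, seed=1)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        assert res.point_r == pytest.approx(1.0)

    def test_seed_reproducibility(self, rng):
        x, y = rng.normal(size=(2, 25))
        a = bootstrap_correlation(x, y, b=500, seed=42)
        b = bootstrap_correlation(x, y, b=500, seed=42)
        c = bootstrap_correlation(x, y, b=500, seed=43)
        assert (a.ci_low, a.ci_high, a.replicate_summary) == (b.ci_low, b.ci_high,
                                                              b.replicate_summary)
        assert a.ci_low != c.ci_low

    def test_degenerate_replicates_counted(self):
        # x has a single repeated value dominating: some resamples are constant
        res = bootstrap_correlation([1.0, 1.0, 2.0], [1.0, 2.0, 3.0], b=2000, seed=0)
        assert 0 < res.n_degenerate < res.b  # counted, not silently dropped

    def test_median_summary_option(self, rng):
        x, y = rng.normal(size=(2, 20))
        res = bootstrap_correlation(x, y, b=300, seed=5, summary="median")
        assert res.summary == "median" and -1 <= res.replicate_summary <= 1

    def test_ci_ordering_and_bounds(self, rng):
        x, y = rng.normal(size=(2, 15))
        res = bootstrap_correlation(x, y, b=500, seed=3)
        assert -1 <= res.ci_low <= res.ci_high <= 1


class TestOnewayAnova:
    def test_hand_computed_sums_of_squares(self):
        res = oneway_anova([1, 2, 3, 2, 3, 4, 3, 4, 5],
                           ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        e = res.effects["group"]
        assert e["f"] == pytest.approx(3.0)
        assert (e["df_num"], e["df_den"]) == (2, 6)

    def test_two_groups_equals_squared_t(self, rng):
        a, b = rng.normal(size=(2, 12))
        f = oneway_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 12).effects["group"]["f"]
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_null_design_large_p(self, rng):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        res = oneway_anova(vals, np.repeat(["a", "b", "c"], 4))
        assert res.effects["group"]["p"] > 0.9

    def test_degenerate_grouping_is_error(self):
        with pytest.raises(ValueError):
            oneway_anova([1, 2, 3], ["a", "a", "a"])


class TestTukeyKramer:
    def test_equal_groups_all_nonsignificant(self, rng):
        vals = rng.normal(size=60)
        res = tukey_kramer(vals, np.repeat(["a", "b", "c"], 20))
        assert not res.comparisons["reject"].any()

    def test_shifted_group_flagged_only(self, rng):
        vals = np.r_[rng.normal(size=20), rng.normal(size=20), rng.normal(size=20) + 5]
        res = tukey_kramer(vals, np.repeat(["a", "b", "c"], 20))
        cmp = res.comparisons.set_index(["group1", "group2"])
        assert cmp.loc[("a", "c"), "reject"] and cmp.loc[("b", "c"), "reject"]
        assert not cmp.loc[("a", "b"), "reject"]

    def test_adjusted_p_matches_studentized_range(self, rng):
        # independent check: p_adj = P(Q_{k,df} > |diff| / SE_kramer)
        vals = np.r_[rng.normal(size=8), rng.normal(size=12) + 1, rng.normal(size=10)]
        groups = np.r_[["a"] * 8, ["b"] * 12, ["c"] * 10]
        res = tukey_kramer(vals, groups)
        sizes = {"a": 8, "b": 12, "c": 10}
        msw = sum(
            ((vals[groups == g] - vals[groups == g].mean()) ** 2).sum() for g in sizes
        ) / (30 - 3)
        for _, row in res.comparisons.iterrows():
            ni, nj = sizes[row["group1"]], sizes[row["group2"]]
            se = np.sqrt(msw / 2 * (1 / ni + 1 / nj))
            q = abs(row["mean_diff"]) / se
            expect = sps.studentized_range.sf(q, 3, 30 - 3)
            assert row["p_adj"] == pytest.approx(expect, abs=1e-4)


class TestChiSquare:
    def test_identical_row_proportions_zero_statistic(self):
        res = chi_square_independence([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        res = chi_square_independence([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_expected_margins_match_observed(self):
        res = chi_square_independence([[5, 15], [25, 55]])
        np.testing.assert_allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 10]])

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected"):
            chi_square_independence([[1, 5], [5, 1]])


class TestTwowayAnova:
    def test_balanced_design_matches_closed_form(self, rng):
        # balanced 2x3: type II coincides with textbook sequential SS
        a = np.repeat([0, 1], 15)
        b = np.tile(np.repeat([0, 1, 2], 5), 2)
        y = 1.0 + 0.8 * a + 0.3 * b + rng.normal(size=30)
        res = twoway_anova(y, a, b, names=("A", "B"))
        grand = y.mean()
        ss_a = sum(15 * (y[a == lev].mean() - grand) ** 2 for lev in (0, 1))
        ss_b = sum(10 * (y[b == lev].mean() - grand) ** 2 for lev in (0, 1, 2))
        cell_means = {(i, j): y[(a == i) & (b == j)].mean() for i in (0, 1) for j in (0, 1, 2)}
        ss_res = sum((y[k] - cell_means[(a[k], b[k])]) ** 2 for k in range(30))
        ss_inter = ((y - grand) ** 2).sum() - ss_a - ss_b - ss_res
        df_res = 30 - 2 - 1 - 1  # main-effects model residual: interaction pooled in
        f_a = ss_a / 1 / ((ss_res + ss_inter) / df_res)
        assert res.effects["A"]["f"] == pytest.approx(f_a, rel=1e-10)

    def test_injected_main_effect_detected(self, rng):
        a = rng.integers(0, 2, 200).astype(bool)
        b = rng.integers(0, 3, 200)
        y = rng.normal(100, 10, 200) + 50 * a
        res = twoway_anova(y, a, b, names=("tpo", "period"))
        assert res.effects["tpo"]["p"] < 1e-6
        assert res.effects["period"]["p"] > 0.01
        assert res.ss_type == "II"

    def test_empty_cell_interaction_downgraded(self, rng):
        a = np.array([0] * 10 + [1] * 10)
        b = np.array([0] * 5 + [1] * 5 + [0] * 10)  # cell (1,1) empty
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="interaction"):
            res = twoway_anova(y, a, b, interaction=True)
        assert "factor_a:factor_b" not in res.effects


class TestOls:
    def test_two_point_line(self):
        fit = ols_fit([0, 1], [0, 2])
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(0.0)

    def test_slope_identity_with_r(self, rng):
        x, y = rng.normal(size=(2, 40))
        fit = ols_fit(x, y)
        r = pearson_r(x, y).r
        assert fit.slope == pytest.approx(r * y.std() / x.std(), rel=1e-9)

    def test_single_point_not_estimable(self):
        fit = ols_fit([5.0], [1.0])
        assert not fit.estimable and fit.n == 1

    def test_constant_predictor_not_estimable(self):
        assert not ols_fit([2, 2, 2], [1, 2, 3]).estimable


class TestStratifiedCorrelation:
    def _frame(self, rng, n=120):
        period = np.repeat(["T1", "T2", "T3", "PP"], n // 4)
        ui = rng.uniform(50, 400, n)
        tfqi = rng.uniform(-1, 1, n)
        return pd.DataFrame({"period": period, "ui": ui, "tfqi": tfqi,
                             "tsh": rng.lognormal(0.3, 0.5, n),
                             "ft4": rng.uniform(0.8, 1.8, n)})

    def test_zero_threshold_reduces_to_per_period(self, rng):
        df = self._frame(rng)
        strat = stratified_correlation(df, threshold=0.0, side="above_strict")
        for res in strat:
            sub = df[df["period"] == res.period]
            assert res.r == pytest.approx(pearson_r(sub["tfqi"], sub["ui"]).r)
            assert res.n == len(sub)

    def test_undersized_stratum_reported_not_raised(self, rng):
        df = self._frame(rng)
        df.loc[df["period"] == "PP", "ui"] = 60.0  # nothing above threshold in PP
        strat = stratified_correlation(df, threshold=250.0)
        pp = next(r for r in strat if r.period == "PP")
        assert not pp.estimable and pp.n == 0 and np.isnan(pp.r)

    def test_sides_partition_pairs(self, rng):
        df = self._frame(rng)
        above = stratified_correlation(df, threshold=250.0, side="above_strict")
        below = stratified_correlation(df, threshold=250.0, side="at_or_below")
        for a, b in zip(above, below):
            n_period = (df["period"] == a.period).sum()
            assert a.n + b.n == n_period

    def test_stratum_labels(self, rng):
        strat = stratified_correlation(self._frame(rng), threshold=250.0)
        assert all(r.stratum == "> 250 μg/L" for r in strat)
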