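"""Screened test selection, BH adjustment, Spearman and 2x2 effect measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from brainagemci.stats import (
    CHI_SQUARED,
    KRUSKAL_WALLIS,
    STUDENT_T,
    WELCH_T,
    ContingencyTable2x2,
    bh_adjust,
    compare_groups,
    odds_ratio_ci,
    select_test,
    spearman_matrix,
)


class TestSelectTest:
    def test_normal_equal_variance_selects_student_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        assert select_test([a, b]) == STUDENT_T

    def test_normal_unequal_variance_selects_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 200), rng.normal(0, 4, 200)
        assert select_test([a, b]) == WELCH_T

    def test_non_normal_selects_kruskal_wallis(self):
        rng = np.random.default_rng(1)
        a, b = rng.exponential(1, 200), rng.normal(0, 1, 200)
        assert select_test([a, b]) == KRUSKAL_WALLIS

    def test_categorical_and_multigroup_branches(self):
        rng = np.random.default_rng(0)
        assert select_test([], kind="categorical") == CHI_SQUARED
        groups = [rng.normal(0, 1, 50) for _ in range(3)]
        assert select_test(groups) == KRUSKAL_WALLIS

    def test_tiny_group_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            select_test([np.array([1.0, 2.0]), np.arange(10.0)])

    def test_null_type_one_error_is_nominal(self):
        """Over 1000 null simulations the screened comparison rejects ~5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
            method = select_test([a, b])
            if method == STUDENT_T:
                p = sps.ttest_ind(a, b).pvalue
            elif method == WELCH_T:
                p = sps.ttest_ind(a, b, equal_var=False).pvalue
            else:
                p = sps.kruskal(a, b).pvalue
            rejections += p < 0.05
        assert 0.035 <= rejections / 1000 <= 0.065


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        base = np.arange(20.0)
        df = pd.DataFrame(
            {
                "g": ["x"] * 20 + ["y"] * 20,
                "score": np.concatenate([base, base]),
                "flag": [0, 1] * 20,
            }
        )
        res = {r.variable: r for r in compare_groups(df, "g", ["score", "flag"],
                                                     kinds={"flag": "categorical"})}
        assert res["score"].statistic == pytest.approx(0.0)
        assert res["score"].p_value == pytest.approx(1.0)
        assert res["flag"].p_value == pytest.approx(1.0)

    def test_welch_t_matches_closed_form_from_group_moments(self):
        """Two samples with the published K-MMSE moments give t ~ 3.50."""

        def exact_moment_sample(mean, sd, n, seed):
            x = np.random.default_rng(seed).normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = exact_moment_sample(26.25, 3.90, 56, 1)
        b = exact_moment_sample(23.17, 4.20, 35, 2)
        t_expected = (26.25 - 23.17) / np.sqrt(3.90**2 / 56 + 4.20**2 / 35)
        t_obs = sps.ttest_ind(a, b, equal_var=False).statistic
        assert t_obs == pytest.approx(t_expected, abs=1e-9)
        assert t_expected == pytest.approx(3.50, abs=0.01)

    def test_three_level_grouping_uses_kruskal_wallis(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 30), "v": rng.normal(size=90)}
        )
        (res,) = compare_groups(df, "g", ["v"])
        assert res.method == KRUSKAL_WALLIS

    def test_adjusted_p_at_least_raw_p(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b"], 40)}
            | {f"v{i}": rng.normal(size=80) for i in range(5)}
        )
        for res in compare_groups(df, "g", [f"v{i}" for i in range(5)], adjust=True):
            assert res.adjusted_p >= res.p_value - 1e-12


def brute_force_bh(p):
    """Independent step-up oracle: adj_i = min over j>=i of m*p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_matches_brute_force_and_is_monotone(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert all(np.diff(np.asarray(adj)[order]) >= -1e-12)


def brute_force_spearman(x, y):
    """Mid-rank rho by the Pearson-on-ranks definition."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfectly_monotone_pairs(self):
        s = pd.DataFrame({"t": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        v = pd.DataFrame(
            {"up": [2.0, 4, 9, 16, 30], "down": [5.0, 4, 3, 2, 1]},
            index=list("abcde"),
        )
        rho, p = spearman_matrix(s, v)
        assert rho.at["t", "up"] == pytest.approx(1.0)
        assert rho.at["t", "down"] == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force(self):
        x = np.array([1.0, 2, 2, 3, 3, 3, 4, 5])
        y = np.array([2.0, 1, 3, 3, 5, 4, 4, 6])
        s = pd.DataFrame({"t": x})
        v = pd.DataFrame({"r": y})
        rho, _ = spearman_matrix(s, v)
        assert rho.at["t", "r"] == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_constant_variable_is_missing_and_pairwise_complete(self):
        s = pd.DataFrame({"const": [1.0] * 8, "t": np.arange(8.0)})
        v = pd.DataFrame({"r": np.arange(8.0) ** 2})
        v.loc[0, "r"] = np.nan  # pairwise-complete drops only this pair
        rho, _ = spearman_matrix(s, v)
        assert np.isnan(rho.at["const", "r"])
        assert rho.at["t", "r"] == pytest.approx(1.0)


class TestOddsRatio:
    def test_study_counts_reproduce_printed_interval(self):
        res = odds_ratio_ci(ContingencyTable2x2(32, 34, 3, 22))
        assert round(res.odds_ratio, 2) == 6.90
        assert round(res.ci_lower, 2) == 1.88
        assert round(res.ci_upper, 2) == 25.31
        assert not res.haldane_corrected

    def test_null_table(self):
        res = odds_ratio_ci(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_lower < 1 < res.ci_upper

    def test_zero_cell_gets_haldane_correction(self):
        res = odds_ratio_ci(ContingencyTable2x2(5, 5, 0, 10))
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 10.5) / (5.5 * 0.5))

    def test_zero_margin_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_ci(ContingencyTable2x2(0, 10, 0, 10))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_swap_symmetries(self, counts):
        a, b, c, d = counts
        base = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
        both = odds_ratio_ci(ContingencyTable2x2(d, c, b, a))  # rows+cols swapped
        rows = odds_ratio_ci(ContingencyTable2x2(c, d, a, b))  # rows swapped
        assert both.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        assert rows.odds_ratio == pytest.approx(1 / base.odds_ratio, rel=1e-12)

    def test_against_independent_implementation(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = Table2x2(np.array([[32, 34], [3, 22]]))
        res = odds_ratio_ci(ContingencyTable2x2(32, 34, 3, 22))
        assert res.odds_ratio == pytest.approx(t.oddsratio, rel=1e-12)
        lo, hi = t.oddsratio_confint(0.05)
        assert res.ci_lower == pytest.approx(lo, rel=1e-9)
        assert res.ci_upper == pytest.approx(hi, rel=1e-9)
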