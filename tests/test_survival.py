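"""Kaplan-Meier, log-rank and Cox against hand-coded oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from brainagemci.brainage import ScoringConfig, compute_brain_age
from brainagemci.survival import (
    SurvivalInput,
    cox_fit,
    cox_score_test_binary,
    km_estimate,
    logrank_test,
    stratified_analysis,
    survival_input_from_records,
)


def hand_logrank_two_group(times, events, groups):
    """Textbook O-E log-rank with hypergeometric variance (group-0 arm)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == groups[0])).sum()
        d = (events & (times == t)).sum()
        d0 = (events & (times == t) & (groups == groups[0])).sum()
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(SurvivalInput([12, 24, 36], [False, False, False]))
        assert curve.times.size == 0
        assert curve.at(36.0) == 1.0

    def test_hand_computed_three_subject_curve(self):
        curve = km_estimate(SurvivalInput([6, 12, 18], [True, False, True]))
        np.testing.assert_allclose(curve.times, [6, 18])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 1])
        assert curve.at(5.9) == 1.0
        assert curve.at(10.0) == pytest.approx(2 / 3)

    def test_mass_point_drops_to_zero(self):
        curve = km_estimate(SurvivalInput([10] * 5, [True] * 5))
        np.testing.assert_allclose(curve.times, [10])
        assert curve.at(10.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(1, 35, 40)
        curve = km_estimate(SurvivalInput(t, np.ones(40, bool)))
        for q in (5.0, 15.0, 30.0):
            assert curve.at(q) == pytest.approx(np.mean(t > q))

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalInput([0.0, 5.0], [True, True])


class TestLogRank:
    def test_duplicated_stratum_is_exact_null(self):
        t = [5, 10, 15, 20.0] * 2
        e = [True, False, True, True] * 2
        labels = ["a"] * 4 + ["b"] * 4
        stat, df, p = logrank_test(SurvivalInput(t, e, labels))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_six_subject_toy_agrees_with_permutation_oracle(self):
        """Statistic equals the hand O-E formula for every label assignment."""
        times = np.array([3.0, 7.0, 11.0, 16.0, 24.0, 30.0])
        events = np.array([True, True, False, True, True, False])
        for combo in itertools.combinations(range(6), 3):
            labels = np.array(["b"] * 6)
            labels[list(combo)] = "a"
            stat, _, _ = logrank_test(SurvivalInput(times, events, labels))
            oracle = hand_logrank_two_group(times, events, labels)
            assert stat == pytest.approx(oracle, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        t = rng.uniform(1, 36, 30)
        e = rng.random(30) < 0.6
        lab = np.where(rng.random(30) < 0.5, "x", "y")
        s1, _, p1 = logrank_test(SurvivalInput(t, e, lab))
        swapped = np.where(lab == "x", "y", "x")
        s2, _, p2 = logrank_test(SurvivalInput(t, e, swapped))
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_requires_two_strata_and_an_event(self):
        with pytest.raises(ValueError, match="two strata"):
            logrank_test(SurvivalInput([5, 6], [True, True], ["a", "a"]))
        with pytest.raises(ValueError, match="event"):
            logrank_test(SurvivalInput([5, 6], [False, False], ["a", "b"]))


def hand_partial_loglik(beta, times, events, x):
    """Cox partial log-likelihood, single covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    toy_times = np.array([2.0, 5.0, 7.0, 11.0, 14.0, 20.0, 27.0, 33.0])
    toy_events = np.array([True, True, False, True, True, True, False, True])
    toy_x = np.array([1.0, 1, 0, 1, 0, 0, 1, 0])

    def test_log_hr_matches_grid_search_partial_likelihood(self):
        fit = cox_fit(
            SurvivalInput(self.toy_times, self.toy_events),
            pd.DataFrame({"x": self.toy_x}),
        )
        grid = np.linspace(-4, 4, 80001)
        ll = [hand_partial_loglik(b, self.toy_times, self.toy_events, self.toy_x)
              for b in grid]
        beta_hat = grid[int(np.argmax(ll))]
        assert np.log(fit.loc["x", "hr"]) == pytest.approx(beta_hat, abs=1e-4)

    def test_score_test_at_zero_equals_logrank(self):
        """Classical identity for one binary covariate without ties."""
        inp = SurvivalInput(self.toy_times, self.toy_events)
        score = cox_score_test_binary(inp, self.toy_x)
        labels = np.where(self.toy_x > 0, "a", "b")
        stat, _, _ = logrank_test(
            SurvivalInput(self.toy_times, self.toy_events, labels)
        )
        assert score == pytest.approx(stat, abs=1e-8)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(77)
        n = 500
        t = np.minimum(rng.exponential(30, n), 36.0)
        e = t < 36.0
        x = rng.random(n) < 0.5
        fit = cox_fit(SurvivalInput(t, e), pd.DataFrame({"x": x.astype(float)}))
        assert 0.8 < fit.loc["x", "hr"] < 1.25

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_fit(
                SurvivalInput(self.toy_times, self.toy_events),
                pd.DataFrame({"x": self.toy_x, "x2": self.toy_x}),
            )

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(
                SurvivalInput([5.0, 9.0, 36.0], [True, False, False]),
                pd.DataFrame({"a": [1.0, 0, 1], "b": [0.0, 1, 1]}),
            )


class TestStratified:
    def test_eight_groups_partition_cohort(self, cohort, scored):
        records, _, _ = cohort
        results, _, _ = scored
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stratified_analysis(records, results)
        assert sum(out["four_group"].sizes.values()) == len(records)
        assert sum(out["eight_group"].sizes.values()) == len(records)
        assert out["eight_group"].df == len(out["eight_group"].sizes) - 1
        for res in out.values():
            assert 0 <= res.p_value <= 1

    def test_single_direction_collapses_with_warning(self, cohort):
        records, _, _ = cohort
        cfg = ScoringConfig()
        results = [
            compute_brain_age(r.subject_id, r.age_scan, -0.4, {"a": False},
                              {"a": 0.6}, cfg)
            for r in records
        ]
        with pytest.warns(UserWarning, match="collapses"):
            out = stratified_analysis(records, results)
        assert set(out["eight_group"].sizes) == {
            f"{s}_younger" for s in out["four_group"].sizes
        }

    def test_censored_beyond_followup_rejected(self, cohort):
        with pytest.raises(ValueError, match="36"):
            SurvivalInput([40.0], [False])
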