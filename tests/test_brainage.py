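"""Brain-age scoring: weights, atrophy flags, gap, bound and consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainagemci.brainage import (
    BA_DOWN,
    BA_UP,
    OLDER,
    YOUNGER,
    ScoringConfig,
    WeightSet,
    classify_cohort,
    compute_brain_age,
    compute_gap,
    compute_weights,
    detect_atrophic,
    severity,
)
from brainagemci.cohort_io import Roi, RoiVolumeTable, EXPANDS, SHRINKS
from brainagemci.normative import adjust_table, fit_normative

HIPPO = Roi("hippocampus_l", "left", SHRINKS)
VENT = Roi("inf_lat_ventricle_l", "left", EXPANDS)
CFG = ScoringConfig()


class TestWeights:
    def test_effect_size_ratio_normalization(self):
        # CU spread gives pooled SD sqrt(2); CI shifts of sqrt(2) and 3*sqrt(2)
        # give Cohen's d of exactly 1 and 3, hence weights 0.25 / 0.75
        cu = pd.DataFrame({"a": [-1.0, 1.0], "b": [-1.0, 1.0]})
        s = np.sqrt(2)
        ci = pd.DataFrame({"a": [s - 1, s + 1], "b": [3 * s - 1, 3 * s + 1]})
        ws = compute_weights(cu, ci)
        assert ws.weights["a"] == pytest.approx(0.25)
        assert ws.weights["b"] == pytest.approx(0.75)
        assert sum(ws.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_fall_back_to_uniform(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 12)))
        data.columns = [f"roi{i}" for i in range(12)]
        with pytest.warns(UserWarning, match="uniform"):
            ws = compute_weights(data, data.copy())
        assert ws.degenerate
        assert all(w == pytest.approx(1 / 12) for w in ws.weights.values())

    def test_sign_captures_expansion_direction(self):
        cu = pd.DataFrame({"vent": [1.0, 1.2, 0.8, 1.1]})
        ci = pd.DataFrame({"vent": [2.0, 2.2, 1.8, 2.1]})
        ws = compute_weights(cu, ci)
        assert ws.signs["vent"] == 1


class TestAtrophyRule:
    @pytest.mark.parametrize(
        "pct,roi,expected",
        [
            (0.049, HIPPO, True),  # just inside the bottom-5% tail
            (0.05, HIPPO, False),  # boundary is strict
            (0.5, HIPPO, False),
            (0.96, VENT, True),  # mirrored top tail for expanding structures
            (0.95, VENT, False),
            (0.049, VENT, False),
        ],
    )
    def test_flag_tail_conventions(self, pct, roi, expected):
        assert detect_atrophic(pct, roi, CFG) is expected

    def test_severity_examples_and_monotonicity(self):
        assert severity(0.5, HIPPO) == pytest.approx(0.5)
        assert severity(0.01, HIPPO) == pytest.approx(0.99)
        assert severity(0.99, VENT) == pytest.approx(0.99)
        grid = np.linspace(0.01, 0.99, 99)
        sh = [severity(p, HIPPO) for p in grid]
        ex = [severity(p, VENT) for p in grid]
        assert all(a >= b for a, b in zip(sh, sh[1:]))  # worse with lower pct
        assert all(a <= b for a, b in zip(ex, ex[1:]))


def uniform_weights(rois):
    n = len(rois)
    return WeightSet({r: 1 / n for r in rois}, {r: -1 for r in rois}, 10, 10)


class TestGapAndBrainAge:
    def test_extremes(self):
        ws = uniform_weights(["a", "b"])
        assert compute_gap(ws, {"a": 0, "b": 0}, {"a": False, "b": False}) == -1.0
        assert compute_gap(ws, {"a": 1, "b": 1}, {"a": True, "b": True}) == 1.0

    def test_hand_computed_gap(self):
        ws = uniform_weights(["a", "b"])
        g = compute_gap(ws, {"a": 0.9, "b": 0.4}, {"a": True, "b": False})
        assert g == pytest.approx(0.65)

    @pytest.mark.parametrize(
        "g,expected_ba,expected_dir",
        [(-1.0, 63.0, YOUNGER), (1.0, 77.0, OLDER), (0.0, 70.0, YOUNGER)],
    )
    def test_theta_bounds_and_tie_rule(self, g, expected_ba, expected_dir):
        res = compute_brain_age("s", 70.0, g, {"a": g > 0}, {"a": abs(g)}, CFG)
        assert res.brain_age == pytest.approx(expected_ba)
        assert res.direction == expected_dir
        assert res.age_delta == pytest.approx(expected_ba - 70.0)


@settings(derandomize=True, max_examples=200)
@given(
    pcts=st.lists(st.floats(0.001, 0.999), min_size=12, max_size=12),
    age=st.floats(50.0, 95.0),
)
def test_bound_and_branch_consistency_property(pcts, age):
    """|BA - age| <= theta and the three branch encodings always agree."""
    rois = [HIPPO if i % 2 == 0 else VENT for i in range(12)]
    names = [f"roi{i}" for i in range(12)]
    ws = uniform_weights(names)
    flags = {n: detect_atrophic(p, r, CFG) for n, r, p in zip(names, rois, pcts)}
    sev = {n: severity(p, r) for n, r, p in zip(names, rois, pcts)}
    g = compute_gap(ws, sev, flags)
    res = compute_brain_age("s", age, g, flags, sev, CFG)
    assert abs(res.brain_age - age) <= CFG.theta + 1e-9
    assert (res.branch == BA_UP) == (g > 0) == any(flags.values())
    assert (res.direction == OLDER) == (res.brain_age > age)


def test_gap_monotone_in_shrinking_roi_percentile():
    names = ["a", "b"]
    ws = uniform_weights(names)
    gaps = []
    for p in np.linspace(0.01, 0.99, 50):
        flags = {"a": detect_atrophic(p, HIPPO, CFG), "b": False}
        sev = {"a": severity(p, HIPPO), "b": 0.3}
        gaps.append(compute_gap(ws, sev, flags))
    assert all(a >= b for a, b in zip(gaps, gaps[1:]))


def test_scale_equivariance_of_adjustment_and_gap():
    """Multiplying all raw volumes by a constant changes nothing downstream."""
    rng = np.random.default_rng(5)
    ids = [f"R{i}" for i in range(80)]
    ages = pd.Series(rng.uniform(55, 90, 80), index=ids)
    sexes = pd.Series(["female", "male"] * 40, index=ids)
    rois = tuple(
        Roi(f"roi{i}", "left", SHRINKS if i % 2 else EXPANDS) for i in range(12)
    )
    base = pd.DataFrame(
        10 + rng.normal(size=(80, 12)), index=ids, columns=[r.name for r in rois]
    )
    for k in (1.0, 3.7):
        model = fit_normative(RoiVolumeTable(k * base, rois), ages, sexes)
        z, pct = adjust_table(RoiVolumeTable(k * base, rois), ages, sexes, model)
        if k == 1.0:
            z_ref, pct_ref = z, pct
    pd.testing.assert_frame_equal(z, z_ref, atol=1e-9, rtol=0)
    pd.testing.assert_frame_equal(pct, pct_ref, atol=1e-9, rtol=0)


class TestClassification:
    def test_partition_conserves_cohort(self, classification):
        assert classification.n == 91
        assert sum(classification.group_sizes.values()) == 91

    def test_all_younger_leaves_older_groups_empty(self):
        results = [
            compute_brain_age(f"s{i}", 70.0, -0.5, {"a": False}, {"a": 0.5}, CFG)
            for i in range(6)
        ]
        conv = {f"s{i}": i % 2 == 0 for i in range(6)}
        cls = classify_cohort(results, conv)
        assert cls.group_sizes[2] == cls.group_sizes[4] == 0
        assert cls.group_sizes[1] + cls.group_sizes[3] == 6
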