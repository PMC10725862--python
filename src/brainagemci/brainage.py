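"""The bounded volumetric brain-age score.

The score condenses 12 age/sex-adjusted regional volumes into a single
age-like number confined to chronological age +/- theta years (theta = 7 by
default):

* **Weights** ``w_c``: per-ROI normalized |Cohen's d| between cognitively
  impaired (CI) and cognitively unimpaired (CU) groups on the adjusted
  scale; they sum to 1 and quantify how discriminative each region is.
* **Atrophic region**: a region whose adjusted volume falls in the reference
  bottom 5th percentile (top 5th for expanding structures such as the
  inferior lateral ventricles).  Strictly below/above the boundary.
* **Severity** ``s_c`` in [0, 1]: the continuous companion of the flag — the
  depth into the abnormal tail (1 - pct for shrinking, pct for expanding
  regions), so the weighted sum over ROIs is well defined on a common scale.
* **Age gap** ``g`` in [-1, 1]: with G = sum_c w_c * s_c, the presence of at
  least one atrophic region selects the ageing branch (g = +G, "BA_up");
  its absence selects the rejuvenating branch (g = -(1 - G), "BA_down").
* **Brain age**: BA = age_at_scan + theta * g, hence |BA - age| <= theta.

A subject is "older by brain age" iff BA > chronological age; the tie
BA == age is classified younger (conservative for the older-group risk
claim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Roi, RoiVolumeTable, SubjectRecord, SHRINKS
from .normative import NormativeModel, adjust_table

BA_UP = "BA_up"
BA_DOWN = "BA_down"
OLDER = "older"
YOUNGER = "younger"


@dataclass
class ScoringConfig:
    """Tunables of the brain-age formula.

    theta: the half-width of the brain-age band in years; atrophy_percentile:
    the abnormal tail mass per region.
    """

    theta: float = 7.0
    atrophy_percentile: float = 0.05

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.atrophy_percentile < 0.5:
            raise ValueError("atrophy_percentile must lie in (0, 0.5)")


@dataclass
class WeightSet:
    """Normalized per-ROI weights with CI-vs-CU direction signs."""

    weights: dict[str, float]
    signs: dict[str, int]  # sign of mean(CI) - mean(CU) on the adjusted scale
    n_cu: int
    n_ci: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


@dataclass
class BrainAgeResult:
    """Per-subject brain-age outcome."""

    subject_id: str
    age_scan: float
    atrophic_flags: dict[str, bool]
    severities: dict[str, float]
    gap: float  # g in [-1, 1]
    brain_age: float
    branch: str  # BA_UP | BA_DOWN
    direction: str  # OLDER | YOUNGER

    @property
    def age_delta(self) -> float:
        """BA minus chronological age at scan (years)."""
        return self.brain_age - self.age_scan


def compute_weights(
    cu_adjusted: pd.DataFrame, ci_adjusted: pd.DataFrame
) -> WeightSet:
    """Derive ROI weights from CU/CI differences on the adjusted scale.

    Raw weight per ROI is |Cohen's d| (pooled-SD standardized mean
    difference) between CI and CU; weights are normalized to sum 1.  If every
    ROI shows zero difference the set degenerates to uniform weights with a
    warning, so pipelines on null data still run.
    """
    if cu_adjusted.empty or ci_adjusted.empty:
        raise ValueError("both CU and CI groups must be non-empty")
    if list(cu_adjusted.columns) != list(ci_adjusted.columns):
        raise ValueError("CU and CI tables must share the ROI columns")
    rois = list(cu_adjusted.columns)
    n1, n2 = len(cu_adjusted), len(ci_adjusted)
    raw, signs = {}, {}
    for roi in rois:
        a = cu_adjusted[roi].to_numpy(dtype=float)
        b = ci_adjusted[roi].to_numpy(dtype=float)
        s1 = a.var(ddof=1) if n1 > 1 else 0.0
        s2 = b.var(ddof=1) if n2 > 1 else 0.0
        pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / max(n1 + n2 - 2, 1))
        diff = b.mean() - a.mean()
        if pooled == 0:
            if diff != 0:
                raise ValueError(f"zero pooled SD with nonzero difference for ROI {roi}")
            raw[roi] = 0.0
        else:
            raw[roi] = abs(diff / pooled)
        signs[roi] = int(np.sign(diff))
    total = sum(raw.values())
    if total == 0:
        warnings.warn(
            "no CU/CI volumetric difference in any ROI; falling back to uniform weights",
            stacklevel=2,
        )
        w = {roi: 1.0 / len(rois) for roi in rois}
        return WeightSet(w, signs, n1, n2, degenerate=True)
    w = {roi: raw[roi] / total for roi in rois}
    # exact renormalization against accumulated float error
    s = sum(w.values())
    w = {roi: v / s for roi, v in w.items()}
    return WeightSet(w, signs, n1, n2)


def detect_atrophic(pct: float, roi: Roi, config: ScoringConfig) -> bool:
    """Is the region atrophic, i.e. in the abnormal 5% tail of the reference?

    Shrinking regions flag strictly below the ``atrophy_percentile``
    boundary; expanding regions flag strictly above its mirror.  A percentile
    exactly on the boundary is not flagged.
    """
    if not 0 < pct < 1:
        raise ValueError("pct must lie strictly inside (0, 1)")
    if roi.effect_direction == SHRINKS:
        return pct < config.atrophy_percentile
    return pct > 1 - config.atrophy_percentile


def severity(pct: float, roi: Roi) -> float:
    """Continuous atrophy severity in [0, 1]: tail-percentile deficit."""
    if not 0 < pct < 1:
        raise ValueError("pct must lie strictly inside (0, 1)")
    return 1 - pct if roi.effect_direction == SHRINKS else pct


def compute_gap(
    weights: WeightSet,
    severities: Mapping[str, float],
    atrophic_flags: Mapping[str, bool],
) -> float:
    """Weighted atrophy burden mapped to the signed gap g in [-1, 1].

    G = sum_c w_c s_c in [0, 1]; any atrophic flag selects the ageing branch
    g = +G, otherwise g = -(1 - G).
    """
    G = sum(weights.weights[roi] * severities[roi] for roi in weights.weights)
    if any(atrophic_flags.values()):
        return G
    return -(1.0 - G)


def compute_brain_age(
    subject_id: str,
    age_scan: float,
    gap: float,
    atrophic_flags: Mapping[str, bool],
    severities: Mapping[str, float],
    config: ScoringConfig,
) -> BrainAgeResult:
    """BA = age + theta * g, with branch and older/younger classification."""
    if abs(gap) > 1 + 1e-12:
        raise ValueError("|g| must not exceed 1")
    ba = age_scan + config.theta * gap
    return BrainAgeResult(
        subject_id=subject_id,
        age_scan=age_scan,
        atrophic_flags=dict(atrophic_flags),
        severities=dict(severities),
        gap=gap,
        brain_age=ba,
        branch=BA_UP if any(atrophic_flags.values()) else BA_DOWN,
        direction=OLDER if ba > age_scan else YOUNGER,
    )


def score_cohort(
    records: Sequence[SubjectRecord],
    volumes: RoiVolumeTable,
    model: NormativeModel,
    weights: WeightSet,
    config: ScoringConfig | None = None,
) -> list[BrainAgeResult]:
    """Score every subject that has a complete volume row.

    Subjects missing from the volume table are skipped with a warning (scan
    unusable); everyone else gets flags, severities, gap and brain age.
    """
    config = config or ScoringConfig()
    by_roi = {r.name: r for r in volumes.rois}
    ages = pd.Series({r.subject_id: r.age_scan for r in records})
    sexes = pd.Series({r.subject_id: r.sex for r in records})
    scored_ids = [r.subject_id for r in records if r.subject_id in volumes.volumes.index]
    missing = [r.subject_id for r in records if r.subject_id not in volumes.volumes.index]
    if missing:
        warnings.warn(
            f"{len(missing)} subject(s) lack ROI volumes and are not scored: {missing[:5]}...",
            stacklevel=2,
        )
    sub = RoiVolumeTable(volumes.volumes.loc[scored_ids], volumes.rois)
    _, pct = adjust_table(sub, ages, sexes, model)
    results = []
    for sid in scored_ids:
        flags = {
            roi: detect_atrophic(float(pct.at[sid, roi]), by_roi[roi], config)
            for roi in pct.columns
        }
        sev = {roi: severity(float(pct.at[sid, roi]), by_roi[roi]) for roi in pct.columns}
        g = compute_gap(weights, sev, flags)
        results.append(
            compute_brain_age(sid, float(ages.loc[sid]), g, flags, sev, config)
        )
    return results


@dataclass
class CohortClassification:
    """Older/younger x converter/non-converter cross-tabulation.

    Group numbering follows the subgroup analysis convention:
    1 = younger non-converters, 2 = older non-converters,
    3 = younger converters,     4 = older converters.
    """

    group_sizes: dict[int, int]
    members: dict[int, list[str]] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.group_sizes.values())

    def counts_2x2(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (older-conv, older-nonconv, younger-conv, younger-nonconv)."""
        g = self.group_sizes
        return g[4], g[2], g[3], g[1]


def classify_cohort(
    results: Sequence[BrainAgeResult], converted: Mapping[str, bool]
) -> CohortClassification:
    """Cross-tabulate brain-age direction against conversion outcome."""
    sizes = {1: 0, 2: 0, 3: 0, 4: 0}
    members: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for res in results:
        conv = bool(converted[res.subject_id])
        older = res.direction == OLDER
        group = 1 + (1 if older else 0) + (2 if conv else 0)
        sizes[group] += 1
        members[group].append(res.subject_id)
    return CohortClassification(sizes, members)


def results_frame(results: Sequence[BrainAgeResult]) -> pd.DataFrame:
    """Brain-age results as a DataFrame (one flag column per ROI)."""
    rows = []
    for r in results:
        d = {
            "age_scan": r.age_scan,
            "gap": r.gap,
            "brain_age": r.brain_age,
            "age_delta": r.age_delta,
            "branch": r.branch,
            "direction": r.direction,
        }
        for roi, flag in r.atrophic_flags.items():
            d[f"atrophic_{roi}"] = flag
        rows.append(pd.Series(d, name=r.subject_id))
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df
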