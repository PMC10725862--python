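"""Group-comparison machinery: screened test selection, BH adjustment,
Spearman correlation matrices and 2x2 effect measures.

Test selection mirrors standard clinical-table practice: Shapiro-Wilk
normality screening per group and Levene variance screening (both at
alpha = 0.05) route a continuous variable to Student's t, Welch's t or the
Kruskal-Wallis test; categorical variables go to the chi-squared test; more
than two groups always go to Kruskal-Wallis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SCREEN_ALPHA = 0.05

STUDENT_T = "student_t"
WELCH_T = "welch_t"
KRUSKAL_WALLIS = "kruskal_wallis"
CHI_SQUARED = "chi_squared"


@dataclass
class ComparisonResult:
    variable: str
    method: str
    statistic: float
    p_value: float
    group_summaries: dict[str, str]
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ContingencyTable2x2:
    """Counts (a, b) / (c, d) with row/column labels.

    Rows are the exposure (e.g. older/younger by brain age), columns the
    outcome (converted / not converted).
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("event", "no_event")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or int(x) != x for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table must contain at least one observation")


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    confidence: float
    haldane_corrected: bool


def select_test(groups: Sequence[np.ndarray], kind: str = "continuous") -> str:
    """Choose the comparison test for one variable.

    Categorical -> chi-squared.  Continuous with > 2 groups -> Kruskal-Wallis.
    Two continuous groups: Shapiro-Wilk on each (alpha 0.05); any rejection
    -> Kruskal-Wallis; both normal -> Levene (alpha 0.05) decides Student's t
    (equal variance) vs Welch's t.
    """
    if kind == "categorical":
        return CHI_SQUARED
    if kind != "continuous":
        raise ValueError(f"unknown variable kind {kind!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 3:
            raise ValueError("each group needs at least 3 observations")
    if len(groups) > 2:
        return KRUSKAL_WALLIS
    for g in groups:
        if sps.shapiro(g).pvalue < SCREEN_ALPHA:
            return KRUSKAL_WALLIS
    if sps.levene(*groups, center="mean").pvalue < SCREEN_ALPHA:
        return WELCH_T
    return STUDENT_T


def _run_test(method: str, groups: Sequence[np.ndarray]) -> tuple[float, float]:
    if method == STUDENT_T:
        r = sps.ttest_ind(groups[0], groups[1], equal_var=True)
    elif method == WELCH_T:
        r = sps.ttest_ind(groups[0], groups[1], equal_var=False)
    elif method == KRUSKAL_WALLIS:
        if all(np.array_equal(g, groups[0]) for g in groups[1:]):
            return 0.0, 1.0  # identical samples: H = 0 exactly, tie-corrected
        r = sps.kruskal(*groups)
    else:
        raise ValueError(f"not a continuous-variable method: {method}")
    return float(r.statistic), float(r.pvalue)


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
    kinds: dict[str, str] | None = None,
    adjust: bool = False,
) -> list[ComparisonResult]:
    """One screened comparison per variable across the levels of ``group_col``.

    Continuous summaries are "mean ± SD", categorical ones "count (pct%)"
    per group.  Missing values are dropped per variable (complete-case).
    With ``adjust=True`` Benjamini-Hochberg adjusted p-values are attached,
    the family being the variables of this one table.
    """
    kinds = kinds or {}
    levels = [lv for lv in data[group_col].dropna().unique()]
    if len(levels) < 2:
        raise ValueError("grouping must have at least two non-empty levels")
    levels = sorted(levels, key=str)
    results: list[ComparisonResult] = []
    for var in variables:
        kind = kinds.get(var, "continuous")
        sub = data[[group_col, var]].dropna()
        groups = [sub.loc[sub[group_col] == lv, var] for lv in levels]
        if any(len(g) == 0 for g in groups):
            raise ValueError(f"empty group for variable {var!r}")
        if kind == "categorical":
            table = pd.crosstab(sub[group_col], sub[var])
            if table.shape[1] < 2:
                stat, p = 0.0, 1.0  # constant outcome: no association testable
            else:
                chi = sps.chi2_contingency(table.to_numpy(), correction=False)
                stat, p = float(chi.statistic), float(chi.pvalue)
            method = CHI_SQUARED
            summaries = {}
            for lv, g in zip(levels, groups):
                pos = int(np.asarray(g, dtype=float).sum())
                summaries[str(lv)] = f"{pos} ({100 * pos / len(g):.2f}%)"
        else:
            arrays = [np.asarray(g, dtype=float) for g in groups]
            method = select_test(arrays, kind="continuous")
            stat, p = _run_test(method, arrays)
            summaries = {
                str(lv): f"{g.mean():.2f} ± {g.std(ddof=1):.2f}"
                for lv, g in zip(levels, arrays)
            }
        results.append(ComparisonResult(var, method, stat, p, summaries))
    if adjust:
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(
    scores: pd.DataFrame, volumes: pd.DataFrame, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for every (test score, ROI volume) pair.

    Pairwise-complete: each cell uses the subjects observed on both
    variables; cells with fewer than ``min_pairs`` pairs or a constant
    variable are NaN.  Mid-rank rho with tie correction, p from the t
    approximation.
    """
    scores, volumes = scores.align(volumes, join="inner", axis=0)
    rho = pd.DataFrame(index=scores.columns, columns=volumes.columns, dtype=float)
    pval = pd.DataFrame(index=scores.columns, columns=volumes.columns, dtype=float)
    for s in scores.columns:
        x_all = scores[s].astype(float)
        for v in volumes.columns:
            y_all = volumes[v].astype(float)
            mask = x_all.notna() & y_all.notna()
            if int(mask.sum()) < min_pairs:
                continue
            x, y = x_all[mask], y_all[mask]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # rho undefined for a constant variable
            r = sps.spearmanr(x, y)
            rho.at[s, v] = float(r.statistic)
            pval.at[s, v] = float(r.pvalue)
    return rho, pval


def odds_ratio_ci(
    table: ContingencyTable2x2, confidence: float = 0.95
) -> OddsRatioResult:
    """Unconditional odds ratio (a*d)/(b*c) with a Wald confidence interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells (flagged in the result).  A zero row or column even after
    correction is undefined and raises.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = False
    if min(a, b, c, d) == 0:
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            raise ValueError("odds ratio undefined: zero row or column")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + confidence / 2)
    log_or = math.log(or_)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_lower=math.exp(log_or - z * se),
        ci_upper=math.exp(log_or + z * se),
        confidence=confidence,
        haldane_corrected=corrected,
    )
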