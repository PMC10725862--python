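"""Conversion-free survival analysis of MCI-to-dementia progression.

"Survival" here is non-conversion: the event is the clinical diagnosis of
dementia, and subjects not converting within the 36-month follow-up window
are administratively censored at 36 months.  Kaplan-Meier estimation,
log-rank comparison and Cox proportional-hazards fitting are provided over
lifelines; Cox ties use the Efron approximation, appropriate for
clinic-visit time resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .brainage import BrainAgeResult, OLDER
from .cohort_io import SubjectRecord

FOLLOWUP_MONTHS = 36.0


@dataclass
class SurvivalInput:
    """Per-subject time-to-event data: months, event flag, stratum label."""

    times: np.ndarray
    events: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("all times must be positive")
        censored = ~self.events
        if np.any(self.times[censored] > FOLLOWUP_MONTHS + 1e-9):
            raise ValueError("censored subjects must have time <= 36 months")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.times.shape:
                raise ValueError("labels must match times in length")


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with at-risk counts and censor marks."""

    times: np.ndarray  # event times (step locations), ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    censor_times: np.ndarray
    label: str | None = None

    def at(self, t: float) -> float:
        """S(t): right-continuous step evaluation; S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(inp: SurvivalInput, label: str | None = None) -> SurvivalCurve:
    """Product-limit survival estimate.

    A censoring tied with an event time is handled by the usual
    censored-after-events convention.
    """
    if inp.times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(inp.times, event_observed=inp.events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in times])
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(inp.times[~inp.events]),
        label=label,
    )


def logrank_test(inp: SurvivalInput) -> tuple[float, int, float]:
    """Log-rank chi-squared over the strata in ``inp.labels``.

    Returns (statistic, degrees of freedom, p).  Requires >= 2 strata and at
    least one event overall.
    """
    if inp.labels is None:
        raise ValueError("stratum labels are required")
    strata = pd.unique(inp.labels)
    if len(strata) < 2:
        raise ValueError("need at least two strata")
    for s in strata:
        if np.sum(inp.labels == s) == 0:
            raise ValueError(f"stratum {s!r} has zero subjects")
    if not inp.events.any():
        raise ValueError("need at least one event overall")
    res = multivariate_logrank_test(inp.times, inp.labels, inp.events)
    return float(res.test_statistic), int(len(strata) - 1), float(res.p_value)


def cox_fit(
    inp: SurvivalInput, covariates: pd.DataFrame, confidence: float = 0.95
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald CIs on log-HR).

    Returns a DataFrame indexed by covariate with columns hr, ci_lower,
    ci_upper, p.  Raises on rank-deficient designs and on events fewer than
    covariates + 1.
    """
    X = covariates.astype(float)
    n_events = int(inp.events.sum())
    if n_events < X.shape[1] + 1:
        raise ValueError(
            f"{n_events} events cannot support {X.shape[1]} covariates"
        )
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear columns)")
    df = X.copy()
    df["_time"] = inp.times
    df["_event"] = inp.events.astype(int)
    cph = CoxPHFitter(alpha=1 - confidence)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as err:  # lifelines ConvergenceError and friends
            raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    summ = cph.summary
    lo = [c for c in summ.columns if c.startswith("exp(coef) lower")][0]
    hi = [c for c in summ.columns if c.startswith("exp(coef) upper")][0]
    out = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_lower": summ[lo],
            "ci_upper": summ[hi],
            "p": summ["p"],
        }
    )
    out.index.name = "covariate"
    return out


def cox_score_test_binary(inp: SurvivalInput, x: np.ndarray) -> float:
    """Score test statistic at beta = 0 for a single covariate.

    U(0)^2 / I(0) from the Cox partial likelihood; with a binary covariate
    and no tied event times this equals the two-group log-rank statistic (a
    classical identity used as a cross-check).
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(inp.times)
    t, e, xv = inp.times[order], inp.events[order], x[order]
    U = 0.0
    info = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        xr = xv[risk]
        m = xr.mean()
        U += xv[i] - m
        info += np.mean((xr - m) ** 2)
    if info == 0:
        raise ValueError("no information at beta = 0")
    return U * U / info


@dataclass
class StratifiedResult:
    """Curves and log-rank test for one stratified design."""

    curves: dict[str, SurvivalCurve]
    statistic: float
    df: int
    p_value: float
    sizes: dict[str, int]
    small_strata: list[str]


def survival_input_from_records(
    records: Sequence[SubjectRecord], labels: Mapping[str, str] | None = None
) -> SurvivalInput:
    times = np.array([r.followup_months for r in records], dtype=float)
    events = np.array([r.converted for r in records], dtype=bool)
    lab = None
    if labels is not None:
        lab = np.array([labels[r.subject_id] for r in records])
    return SurvivalInput(times, events, lab)


def stratified_analysis(
    records: Sequence[SubjectRecord],
    results: Sequence[BrainAgeResult],
    education_cut_years: float = 12.0,
    min_stratum: int = 5,
) -> dict[str, StratifiedResult]:
    """Sex x education and sex x education x brain-age stratified survival.

    Education dichotomized at >= 12 years (high vs low).  Returns the
    4-group and 8-group designs keyed "four_group" / "eight_group"; empty
    design cells are dropped with a warning and strata smaller than
    ``min_stratum`` are flagged.  If no subject carries one brain-age
    direction, the 8-group design collapses onto the 4-group one.
    """
    direction = {r.subject_id: r.direction for r in results}
    scored = [r for r in records if r.subject_id in direction]

    def edu(rec: SubjectRecord) -> str:
        return "highedu" if rec.education_years >= education_cut_years else "lowedu"

    four = {r.subject_id: f"{r.sex}_{edu(r)}" for r in scored}
    eight = {
        r.subject_id: f"{r.sex}_{edu(r)}_{direction[r.subject_id]}" for r in scored
    }
    directions_present = {direction[r.subject_id] for r in scored}
    if len(directions_present) < 2:
        warnings.warn(
            "only one brain-age direction present; the 8-group design collapses "
            "onto the 4-group design",
            stacklevel=2,
        )
    out = {}
    for key, labels in (("four_group", four), ("eight_group", eight)):
        inp = survival_input_from_records(scored, labels)
        present = pd.unique(inp.labels)
        sizes = {str(s): int(np.sum(inp.labels == s)) for s in present}
        small = [s for s, n in sizes.items() if n < min_stratum]
        if small:
            warnings.warn(f"{key}: strata below n={min_stratum}: {small}", stacklevel=2)
        curves = {}
        for s in present:
            mask = inp.labels == s
            curves[str(s)] = km_estimate(
                SurvivalInput(inp.times[mask], inp.events[mask]), label=str(s)
            )
        stat, dof, p = logrank_test(inp)
        out[key] = StratifiedResult(curves, stat, dof, p, sizes, small)
    return out


def curve_frame(curve: SurvivalCurve) -> pd.DataFrame:
    """Export a KM curve as a tidy table (time, survival, at-risk)."""
    return pd.DataFrame(
        {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    )
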