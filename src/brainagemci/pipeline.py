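"""End-to-end analysis orchestration.

One call runs the whole chain — normative fit, weight derivation, brain-age
scoring, four-group classification, demographics comparison table, subgroup
comparisons with BH adjustment, neuropsych x ROI Spearman matrices, the 2x2
conversion odds ratio and the stratified Kaplan-Meier / log-rank survival
analysis — and returns a JSON-serializable results bundle in which every
number is traceable to the operation that produced it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .brainage import (
    BrainAgeResult,
    ScoringConfig,
    WeightSet,
    classify_cohort,
    compute_weights,
    results_frame,
    score_cohort,
)
from .cohort_io import NEUROPSYCH_TESTS, RoiVolumeTable, SubjectRecord, records_frame
from .normative import NormativeModel, adjust_table, fit_normative
from .stats import ContingencyTable2x2, bh_adjust, compare_groups, odds_ratio_ci, spearman_matrix
from .survival import (
    cox_fit,
    stratified_analysis,
    survival_input_from_records,
    logrank_test,
)

#: Screening-to-analysis flow of the study design: subjects recruited, then
#: excluded for (in order) structural lesions / Fazekas > 2, medical or
#: traumatic history, non-AD neurodegenerative causes, follow-up shorter
#: than 36 months, and technically unusable MRI scans.
SCREENING_FLOW: tuple[tuple[str, int], ...] = (
    ("recruited", 211),
    ("structural_lesion_or_wm_change", 42),
    ("tbi_seizure_or_systemic_illness", 2),
    ("other_neurodegenerative_cause", 14),
    ("followup_below_36_months", 46),
    ("mri_technical_artifact", 16),
)


def exclusion_flow() -> dict:
    """Apply the exclusion ledger step by step; returns stagewise remainders."""
    stages = []
    remaining = None
    for name, n in SCREENING_FLOW:
        if remaining is None:
            remaining = n
        else:
            remaining -= n
        stages.append({"stage": name, "n": n, "remaining": remaining})
    return {"stages": stages, "final_n": remaining}


TABLE1_VARIABLES = (
    ("age_onset", "continuous"),
    ("age_diagnosis", "continuous"),
    ("age_scan", "continuous"),
    ("sex", "categorical"),
    ("education_years", "continuous"),
    ("apoe4_carrier", "categorical"),
    ("kmmse", "continuous"),
    ("cdr", "continuous"),
)

SUBGROUP_VARIABLES = ("kmmse", "cdr_sob") + NEUROPSYCH_TESTS


@dataclass
class AnalysisBundle:
    """All outputs of one pipeline run plus a provenance manifest."""

    brainage: pd.DataFrame
    classification: dict
    odds_ratio: dict
    table1: list
    subgroup_comparisons: list
    spearman: dict[str, dict[str, pd.DataFrame]]
    survival: dict
    method_log: list[str]
    manifest: dict

    def to_json(self) -> str:
        payload = {
            "manifest": self.manifest,
            "classification": self.classification,
            "odds_ratio": self.odds_ratio,
            "table1": self.table1,
            "subgroup_comparisons": self.subgroup_comparisons,
            "survival": self.survival,
            "method_log": self.method_log,
        }
        return json.dumps(payload, indent=1, default=_jsonable)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.brainage.to_csv(outdir / "brainage_results.csv")
        for group, mats in self.spearman.items():
            mats["rho"].to_csv(outdir / f"spearman_rho_{group}.csv")
            mats["p"].to_csv(outdir / f"spearman_p_{group}.csv")
        (outdir / "analysis_manifest.json").write_text(self.to_json(), encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in obj.__dict__.items()}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def comparison_to_dict(res) -> dict:
    return {
        "variable": res.variable,
        "method": res.method,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "adjusted_p": res.adjusted_p,
        "group_summaries": res.group_summaries,
    }


def run_analysis(
    records: Sequence[SubjectRecord],
    volumes: RoiVolumeTable,
    reference: RoiVolumeTable,
    reference_ages: pd.Series,
    reference_sexes: pd.Series,
    scoring: ScoringConfig | None = None,
    education_cut_years: float = 12.0,
    seed: int | None = None,
) -> AnalysisBundle:
    """Run the full analysis over one cohort.

    ``reference`` is the cognitively unimpaired sample used both for the
    normative age/sex adjustment and as the CU arm of the weight derivation;
    the study cohort itself is the CI arm.  Deterministic given the inputs.
    """
    scoring = scoring or ScoringConfig()
    log: list[str] = []

    # --- stage: normative fit + weights + scoring ---
    model = fit_normative(
        reference, reference_ages, reference_sexes, scoring.atrophy_percentile
    )
    cu_z, _ = adjust_table(reference, reference_ages, reference_sexes, model)
    ages = pd.Series({r.subject_id: r.age_scan for r in records})
    sexes = pd.Series({r.subject_id: r.sex for r in records})
    ci_z, _ = adjust_table(volumes, ages, sexes, model)
    weights = compute_weights(cu_z, ci_z)
    log.append(
        f"weights: normalized |Cohen's d| over {len(weights.weights)} ROIs "
        f"(CU n={weights.n_cu}, CI n={weights.n_ci})"
    )
    results = score_cohort(records, volumes, model, weights, scoring)
    ba_frame = results_frame(results)

    # --- stage: four-group classification + 2x2 odds ratio ---
    conv = {r.subject_id: r.converted for r in records}
    cls = classify_cohort(results, conv)
    a, b, c, d = cls.counts_2x2()
    or_res = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
    n_scored = cls.n
    n_older, n_younger = a + b, c + d
    classification = {
        "group_sizes": cls.group_sizes,
        "counts_2x2": {"older_conv": a, "older_nonconv": b,
                       "younger_conv": c, "younger_nonconv": d},
        "n_scored": n_scored,
        "rate_older_pct": 100 * a / n_older if n_older else float("nan"),
        "rate_younger_pct": 100 * c / n_younger if n_younger else float("nan"),
        "converter_older_fraction_pct": 100 * a / (a + c) if a + c else float("nan"),
        "cohort_older_fraction_pct": 100 * n_older / n_scored,
        "cohort_conversion_pct": 100 * (a + c) / n_scored,
    }
    odds_ratio = {
        "odds_ratio": or_res.odds_ratio,
        "ci_lower": or_res.ci_lower,
        "ci_upper": or_res.ci_upper,
        "confidence": or_res.confidence,
        "haldane_corrected": or_res.haldane_corrected,
    }

    # --- stage: demographics comparison (converters vs non-converters) ---
    df = records_frame(records)
    df["sex"] = (df["sex"] == "female").astype(float)  # female = 1 for counts
    df["apoe4_carrier"] = df["apoe4_carrier"].astype(float)
    df["conversion_group"] = np.where(df["converted"], "converter", "non_converter")
    table1 = compare_groups(
        df,
        "conversion_group",
        [v for v, _ in TABLE1_VARIABLES],
        kinds=dict(TABLE1_VARIABLES),
    )
    for res in table1:
        log.append(f"table1 {res.variable}: {res.method}")

    # --- stage: subgroup comparisons (groups 1, 2, 4; group 3 too small) ---
    grp = pd.Series(
        {sid: g for g, sids in cls.members.items() for sid in sids}, name="group"
    )
    df4 = df.join(grp)
    keep = df4["group"].isin([1, 2, 4])
    subgroup = []
    if keep.sum() and df4.loc[keep, "group"].nunique() >= 2:
        sub_df = df4.loc[keep].copy()
        sub_df["group"] = sub_df["group"].astype(str)
        subgroup = compare_groups(
            sub_df, "group", list(SUBGROUP_VARIABLES), adjust=True
        )
        for res in subgroup:
            log.append(f"subgroup {res.variable}: {res.method} (BH-adjusted)")

    # --- stage: Spearman matrices per conversion group (figure-1 analogue) ---
    score_cols = ["kmmse", "cdr_sob", "gds_stage", "education_years"] + list(
        NEUROPSYCH_TESTS
    )
    spearman = {}
    for group, mask in (
        ("converter", df["converted"].astype(bool)),
        ("non_converter", ~df["converted"].astype(bool)),
    ):
        ids = df.index[mask].intersection(volumes.volumes.index)
        rho, p = spearman_matrix(
            df.loc[ids, score_cols].astype(float), volumes.volumes.loc[ids]
        )
        spearman[group] = {"rho": rho, "p": p}

    # --- stage: survival ---
    direction = {r.subject_id: r.direction for r in results}
    scored_recs = [r for r in records if r.subject_id in direction]
    surv: dict = {}
    two_group = survival_input_from_records(
        scored_recs, {sid: direction[sid] for sid in direction}
    )
    try:
        stat, dof, p = logrank_test(two_group)
        surv["older_vs_younger"] = {"statistic": stat, "df": dof, "p": p}
    except ValueError as err:
        warnings.warn(f"older-vs-younger log-rank skipped: {err}", stacklevel=2)
    strat = stratified_analysis(scored_recs, results, education_cut_years)
    for key, res in strat.items():
        surv[key] = {
            "statistic": res.statistic,
            "df": res.df,
            "p": res.p_value,
            "sizes": res.sizes,
            "small_strata": res.small_strata,
        }
    # generic Cox fit: brain-age direction + sex + education
    cov = pd.DataFrame(
        {
            "older_by_brain_age": [float(direction[r.subject_id] == "older") for r in scored_recs],
            "male": [float(r.sex == "male") for r in scored_recs],
            "education_years": [r.education_years for r in scored_recs],
        },
        index=[r.subject_id for r in scored_recs],
    )
    try:
        cox = cox_fit(survival_input_from_records(scored_recs), cov)
        surv["cox"] = {
            cov_name: {k: float(v) for k, v in row.items()}
            for cov_name, row in cox.iterrows()
        }
    except (ValueError, RuntimeError) as err:
        surv["cox"] = {"error": str(err)}
        log.append(f"cox fit skipped: {err}")

    manifest = {
        "package": "brainagemci",
        "version": __version__,
        "seed": seed,
        "n_subjects": len(records),
        "n_scored": n_scored,
        "theta": scoring.theta,
        "atrophy_percentile": scoring.atrophy_percentile,
        "education_cut_years": education_cut_years,
        "exclusion_flow": exclusion_flow(),
        "provenance": {
            "classification": "brainage.classify_cohort",
            "odds_ratio": "stats.odds_ratio_ci",
            "table1": "stats.compare_groups",
            "subgroup_comparisons": "stats.compare_groups + stats.bh_adjust",
            "spearman": "stats.spearman_matrix",
            "survival": "survival.km_estimate + survival.logrank_test + survival.cox_fit",
        },
    }
    return AnalysisBundle(
        brainage=ba_frame,
        classification=classification,
        odds_ratio=odds_ratio,
        table1=[comparison_to_dict(r) for r in table1],
        subgroup_comparisons=[comparison_to_dict(r) for r in subgroup],
        spearman=spearman,
        survival=surv,
        method_log=log,
        manifest=manifest,
    )
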