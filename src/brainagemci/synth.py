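"""Synthetic amnestic-MCI cohort generator.

Real volumetric cohorts of this kind are not publicly sharable, so every
stage of the pipeline is exercised on synthetic cohorts that emulate the
study's statistical structure: 91 subjects partitioned into the four
direction x conversion subgroups (22 / 34 / 3 / 32), baseline moments per
conversion group (age at scan 72.04 +/- 9.10 vs 74.51 +/- 7.18 years, K-MMSE
26.25 +/- 3.90 vs 23.17 +/- 4.20, female fraction 51.79% vs 68.57%,
education 9.62 +/- 5.43 years), conversion times uniform on (0, 36] months
and administrative censoring at 36 months.

Regional volumes are drawn from a linear age trend with a sex offset and
Gaussian noise — the same functional family the normative module fits.  Each
subject carries a *designed* brain-age direction: designed-older subjects
get a random subset of regions forced deep into the abnormal tail
(|z| >= 2.5 beyond the boundary), designed-younger subjects have all regions
truncated to the healthy band |z| <= 1.  The margins are wide relative to
the sampling error of an empirical 5th-percentile threshold, so scoring a
generated cohort against a generated reference recovers the designed
direction and hence the designed 2x2 table.

Two conversion modes exist: ``designed`` fixes the subgroup sizes exactly
(the study's observed table); ``stochastic`` keeps the direction margins but
draws conversion per subject at the per-direction rates, which is what the
odds-ratio recovery experiment needs for its confidence intervals to have
non-degenerate coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    DEFAULT_ROIS,
    NEUROPSYCH_TESTS,
    Roi,
    RoiVolumeTable,
    SHRINKS,
    SubjectRecord,
)
from .brainage import ScoringConfig, WeightSet, classify_cohort, score_cohort
from .normative import fit_normative
from .stats import ContingencyTable2x2, odds_ratio_ci


@dataclass(frozen=True)
class RoiGenParams:
    """True generating model of one region: mL at age 70 (female), additive
    male offset, mL/year age slope, residual SD."""

    base: float
    sex_offset: float
    slope: float
    sd: float


#: Plausible adult volumetry (mL); lobes are per hemisphere.
DEFAULT_ROI_PARAMS: dict[str, RoiGenParams] = {
    "hippocampus_l": RoiGenParams(3.4, 0.25, -0.020, 0.35),
    "hippocampus_r": RoiGenParams(3.5, 0.25, -0.020, 0.35),
    "inf_lat_ventricle_l": RoiGenParams(2.6, 0.20, 0.040, 0.35),
    "inf_lat_ventricle_r": RoiGenParams(2.5, 0.20, 0.040, 0.35),
    "frontal_lobe_l": RoiGenParams(75.0, 6.0, -0.30, 6.0),
    "frontal_lobe_r": RoiGenParams(76.0, 6.0, -0.30, 6.0),
    "parietal_lobe_l": RoiGenParams(50.0, 4.0, -0.22, 4.5),
    "parietal_lobe_r": RoiGenParams(51.0, 4.0, -0.22, 4.5),
    "temporal_lobe_l": RoiGenParams(55.0, 4.5, -0.25, 5.0),
    "temporal_lobe_r": RoiGenParams(56.0, 4.5, -0.25, 5.0),
    "occipital_lobe_l": RoiGenParams(30.0, 2.5, -0.12, 3.0),
    "occipital_lobe_r": RoiGenParams(31.0, 2.5, -0.12, 3.0),
}

#: Neuropsych generating moments (base mean, SD, converter shift).  Shifted
#: tests are the ones reported to separate converters from non-converters
#: among the older-by-brain-age subjects; the rest differ only by noise.
DEFAULT_NEUROPSYCH_PARAMS: dict[str, tuple[float, float, float]] = {
    "rcft_immediate": (13.0, 5.0, 0.0),
    "rcft_delayed": (12.0, 5.0, -3.0),
    "rcft_recognition": (18.0, 2.5, -1.5),
    "svlt": (16.0, 4.0, 0.0),
    "cowat_animal": (12.0, 3.5, -2.0),
    "cowat_phonemic": (20.0, 7.0, 0.0),
    "stroop_color": (70.0, 20.0, 0.0),
    "ideomotor_praxis": (4.8, 0.4, -0.4),
    "kbnt": (40.0, 8.0, 0.0),
    "sgds": (5.0, 3.0, 0.0),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Subgroup sizes follow the published four-group table; all moments are
    the published baseline characteristics per conversion group.
    """

    n_subjects: int = 91
    # (younger non-conv, older non-conv, younger conv, older conv)
    subgroup_sizes: tuple[int, int, int, int] = (22, 34, 3, 32)
    age_scan_nonconv: tuple[float, float] = (72.04, 9.10)
    age_scan_conv: tuple[float, float] = (74.51, 7.18)
    kmmse_nonconv: tuple[float, float] = (26.25, 3.90)
    kmmse_conv: tuple[float, float] = (23.17, 4.20)
    female_frac_nonconv: float = 0.5179
    female_frac_conv: float = 0.6857
    education_years: tuple[float, float] = (9.62, 5.43)
    apoe4_frac_nonconv: float = 0.1786
    apoe4_frac_conv: float = 0.1715
    followup_months: float = 36.0
    cdr_sob_shift_conv: float = 0.8  # converter shift of CDR sum-of-boxes
    conversion_mode: str = "designed"  # "designed" | "stochastic"
    #: extra multiplicative conversion risk per sex_edu stratum (stochastic mode)
    stratum_rate_multipliers: dict[str, float] = field(default_factory=dict)
    #: designed atrophic-region count range per older subject (inclusive)
    n_atrophic_nonconv: tuple[int, int] = (1, 3)
    n_atrophic_conv: tuple[int, int] = (2, 6)
    atrophy_depth_z: float = 2.5  # |z| beyond which forced-atrophic regions sit
    healthy_band_z: float = 1.0  # |z| bound of non-atrophic study regions
    null_atrophy: bool = False  # draw all z ~ N(0,1): no designed direction
    n_reference: int = 600
    rois: tuple[Roi, ...] = DEFAULT_ROIS
    roi_params: dict[str, RoiGenParams] = field(
        default_factory=lambda: dict(DEFAULT_ROI_PARAMS)
    )
    neuropsych_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NEUROPSYCH_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subgroup_sizes) != self.n_subjects:
            raise ValueError("subgroup sizes must sum to n_subjects")
        if any(s <= 0 for s in (self.age_scan_nonconv[1], self.age_scan_conv[1],
                                self.kmmse_nonconv[1], self.kmmse_conv[1],
                                self.education_years[1])):
            raise ValueError("all SDs must be positive")
        for frac in (self.female_frac_nonconv, self.female_frac_conv,
                     self.apoe4_frac_nonconv, self.apoe4_frac_conv):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.conversion_mode not in ("designed", "stochastic"):
            raise ValueError("conversion_mode must be 'designed' or 'stochastic'")

    @property
    def rate_older(self) -> float:
        g1, g2, g3, g4 = self.subgroup_sizes
        return g4 / (g2 + g4)

    @property
    def rate_younger(self) -> float:
        g1, g2, g3, g4 = self.subgroup_sizes
        return g3 / (g1 + g3)

    @property
    def true_odds_ratio(self) -> float:
        po, py = self.rate_older, self.rate_younger
        return (po / (1 - po)) / (py / (1 - py))


def _trunc_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    """Rejection-sampled truncated normal (bounds are always far from mass)."""
    out = rng.normal(mean, sd, size=size)
    arr = np.atleast_1d(np.asarray(out, dtype=float))
    bad = (arr < lo) | (arr > hi)
    while bad.any():
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (arr < lo) | (arr > hi)
    return float(arr[0]) if size is None else arr


def _roi_volume(p: RoiGenParams, age: float, male: bool, z: float) -> float:
    return p.base + (p.sex_offset if male else 0.0) + p.slope * (age - 70.0) + p.sd * z


def _positive_volume(
    p: RoiGenParams, age: float, male: bool, z: float, rng: np.random.Generator
) -> float:
    """Resample the noise term in the vanishing tail where v would be <= 0
    (probability ~1e-7 per draw at the default parameters)."""
    v = _roi_volume(p, age, male, z)
    while v <= 0.05:
        v = _roi_volume(p, age, male, float(rng.normal()))
    return v


def generate_reference(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[RoiVolumeTable, pd.Series, pd.Series]:
    """Cognitively unimpaired reference sample for the normative fit.

    Ages uniform on [55, 90], sexes balanced, volume noise fully Gaussian
    (no truncation: the reference defines the percentile scale).
    """
    n = config.n_reference
    ids = [f"REF{i:04d}" for i in range(n)]
    ages = pd.Series(rng.uniform(55, 90, size=n), index=ids)
    sexes = pd.Series(np.where(np.arange(n) % 2 == 0, "female", "male"), index=ids)
    vols = {}
    for roi in config.rois:
        p = config.roi_params[roi.name]
        z = rng.normal(size=n)
        vols[roi.name] = [
            _positive_volume(p, ages.iloc[i], sexes.iloc[i] == "male", z[i], rng)
            for i in range(n)
        ]
    df = pd.DataFrame(vols, index=ids)[[r.name for r in config.rois]]
    df.index.name = "subject_id"
    return RoiVolumeTable(df, config.rois), ages, sexes


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[list[SubjectRecord], RoiVolumeTable, pd.DataFrame]:
    """Generate the study cohort; returns (records, volumes, ground truth).

    The ground-truth sidecar records the designed subgroup, direction and
    number of forced-atrophic regions per subject.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g1, g2, g3, g4 = config.subgroup_sizes

    # designed (direction, converted) per subject
    if config.conversion_mode == "designed":
        design = (
            [("younger", False)] * g1
            + [("older", False)] * g2
            + [("younger", True)] * g3
            + [("older", True)] * g4
        )
    else:
        design = []
        for direction, n_dir, rate in (
            ("younger", g1 + g3, config.rate_younger),
            ("older", g2 + g4, config.rate_older),
        ):
            for _ in range(n_dir):
                design.append((direction, None))  # conversion drawn after sex/edu

    records: list[SubjectRecord] = []
    vol_rows: dict[str, list[float]] = {}
    truth_rows = []

    # designed mode: exact female counts per conversion group (Table-1 style)
    sex_pool: dict[bool, list[str]] = {}
    if config.conversion_mode == "designed":
        for conv, n_grp, frac in (
            (False, g1 + g2, config.female_frac_nonconv),
            (True, g3 + g4, config.female_frac_conv),
        ):
            n_f = int(round(frac * n_grp))
            pool = ["female"] * n_f + ["male"] * (n_grp - n_f)
            rng.shuffle(pool)
            sex_pool[conv] = pool

    for i, (direction, conv) in enumerate(design):
        sid = f"S{i + 1:03d}"
        education = _trunc_normal(rng, *config.education_years, lo=0.0)
        if conv is None:  # stochastic conversion
            # sex drawn at the cohort-average female fraction, conversion at
            # the per-direction rate times any configured stratum multiplier
            frac = (
                (g1 + g2) * config.female_frac_nonconv
                + (g3 + g4) * config.female_frac_conv
            ) / config.n_subjects
            sex = "female" if rng.random() < frac else "male"
            base = config.rate_older if direction == "older" else config.rate_younger
            edu = "highedu" if education >= 12 else "lowedu"
            mult = config.stratum_rate_multipliers.get(f"{sex}_{edu}", 1.0)
            conv = bool(rng.random() < min(base * mult, 1.0))
        else:
            sex = sex_pool[conv].pop()

        age_mom = config.age_scan_conv if conv else config.age_scan_nonconv
        age_scan = _trunc_normal(rng, *age_mom, lo=50.5, hi=95.0)
        age_diagnosis = min(95.0, age_scan + abs(rng.normal(0.25, 0.10)))
        dur_mom = (28.37, 21.50) if conv else (32.61, 30.50)  # months onset->diagnosis
        age_onset = max(50.0, age_diagnosis - _trunc_normal(rng, *dur_mom, lo=0.0) / 12.0)

        km_mom = config.kmmse_conv if conv else config.kmmse_nonconv
        kmmse = int(np.clip(round(rng.normal(*km_mom)), 0, 30))
        cdr = 0.5 + (0.5 if (conv and rng.random() < 0.08) else 0.0)
        cdr_sob = _trunc_normal(
            rng, 1.2 + (config.cdr_sob_shift_conv if conv else 0.0), 0.7, lo=0.5
        )
        gds_stage = int(np.clip(3 + (1 if (conv and rng.random() < 0.4) else 0), 1, 7))
        apoe_frac = config.apoe4_frac_conv if conv else config.apoe4_frac_nonconv
        apoe = bool(rng.random() < apoe_frac)
        neuropsych = {}
        for t in NEUROPSYCH_TESTS:
            mean, sd, shift = config.neuropsych_params[t]
            neuropsych[t] = float(
                _trunc_normal(rng, mean + (shift if conv else 0.0), sd, lo=0.0)
            )
        if conv:
            followup = float(rng.uniform(0.0, config.followup_months))
            followup = max(followup, 0.5)  # conversions happen strictly after baseline
        else:
            followup = config.followup_months

        records.append(
            SubjectRecord(
                subject_id=sid,
                sex=sex,
                education_years=education,
                age_onset=age_onset,
                age_diagnosis=age_diagnosis,
                age_scan=age_scan,
                kmmse=kmmse,
                cdr=cdr,
                cdr_sob=cdr_sob,
                gds_stage=gds_stage,
                neuropsych=neuropsych,
                apoe4_carrier=apoe,
                converted=conv,
                followup_months=followup,
                censored=not conv,
            )
        )

        # --- regional volumes ---
        male = sex == "male"
        roi_names = [r.name for r in config.rois]
        if config.null_atrophy:
            zs = rng.normal(size=len(roi_names))
            n_atro = 0
        else:
            if direction == "older":
                lo_n, hi_n = (
                    config.n_atrophic_conv if conv else config.n_atrophic_nonconv
                )
                n_atro = int(rng.integers(lo_n, hi_n + 1))
                atro_idx = set(rng.choice(len(roi_names), size=n_atro, replace=False))
            else:
                n_atro = 0
                atro_idx = set()
            zs = np.empty(len(roi_names))
            for j, roi in enumerate(config.rois):
                sign = -1.0 if roi.effect_direction == SHRINKS else 1.0
                if j in atro_idx:
                    zs[j] = sign * (config.atrophy_depth_z + abs(rng.normal(0.0, 0.5)))
                else:
                    zs[j] = _trunc_normal(
                        rng, 0.0, 1.0, lo=-config.healthy_band_z, hi=config.healthy_band_z
                    )
        vol_rows[sid] = [
            _positive_volume(config.roi_params[roi.name], age_scan, male, zs[j], rng)
            for j, roi in enumerate(config.rois)
        ]
        truth_rows.append(
            {
                "subject_id": sid,
                "designed_direction": direction,
                "converted": conv,
                "n_atrophic_designed": n_atro,
            }
        )

    for rec in records:
        rec.validate()
    vol_df = pd.DataFrame.from_dict(
        vol_rows, orient="index", columns=[r.name for r in config.rois]
    )
    vol_df.index.name = "subject_id"
    volumes = RoiVolumeTable(vol_df, config.rois)
    volumes.validate()
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return records, volumes, truth


def score_generated_cohort(
    records: Sequence[SubjectRecord],
    volumes: RoiVolumeTable,
    config: GeneratorConfig,
    rng: np.random.Generator,
    scoring: ScoringConfig | None = None,
):
    """Fit the normative model on a fresh reference, derive CU/CI weights and
    score the cohort.  Returns (results, model, weights)."""
    reference, ref_ages, ref_sexes = generate_reference(config, rng)
    model = fit_normative(
        reference, ref_ages, ref_sexes,
        atrophy_percentile=(scoring or ScoringConfig()).atrophy_percentile,
    )
    from .normative import adjust_table  # local import to avoid cycle at module load

    cu_z, _ = adjust_table(reference, ref_ages, ref_sexes, model)
    ages = pd.Series({r.subject_id: r.age_scan for r in records})
    sexes = pd.Series({r.subject_id: r.sex for r in records})
    ci_z, _ = adjust_table(volumes, ages, sexes, model)
    from .brainage import compute_weights

    weights = compute_weights(cu_z, ci_z)
    results = score_cohort(records, volumes, model, weights, scoring)
    return results, model, weights


@dataclass
class RecoveryReport:
    """Monte-Carlo odds-ratio recovery summary."""

    n_replicates: int
    true_odds_ratio: float
    odds_ratios: np.ndarray
    mean_log_or: float
    ci_coverage: float  # fraction of Wald 95% CIs covering the true OR

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "true_odds_ratio": self.true_odds_ratio,
            "mean_log_or": self.mean_log_or,
            "mean_or": float(np.exp(self.mean_log_or)),
            "ci_coverage": self.ci_coverage,
        }


def recovery_experiment(
    config: GeneratorConfig, n_replicates: int, seed: int
) -> RecoveryReport:
    """Generate -> score -> odds-ratio, repeated; report recovery and coverage.

    Each replicate draws a stochastic-conversion cohort, scores it against a
    fresh reference and computes the conversion odds ratio (older vs younger
    by brain age) with its 95% Wald CI.  Coverage is the fraction of CIs
    containing the configured true OR.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    cfg = replace(config, conversion_mode="stochastic")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    ors, covered = [], []
    true_or = cfg.true_odds_ratio
    for child in children:
        rng = np.random.default_rng(child)
        rec_seed = int(rng.integers(0, 2**31 - 1))
        records, volumes, _ = generate_cohort(cfg, seed=rec_seed)
        results, _, _ = score_generated_cohort(records, volumes, cfg, rng)
        conv = {r.subject_id: r.converted for r in records}
        cls = classify_cohort(results, conv)
        a, b, c, d = cls.counts_2x2()
        res = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
        ors.append(res.odds_ratio)
        covered.append(res.ci_lower <= true_or <= res.ci_upper)
    ors = np.asarray(ors)
    return RecoveryReport(
        n_replicates=n_replicates,
        true_odds_ratio=true_or,
        odds_ratios=ors,
        mean_log_or=float(np.mean(np.log(ors))),
        ci_coverage=float(np.mean(covered)),
    )
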