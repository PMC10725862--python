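"""Cohort table I/O and the canonical subject/ROI schema.

Every other module consumes the containers defined here: per-subject clinical
records (demographics, cognition, conversion outcome, follow-up) and a
subjects x ROI table of regional brain volumes in millilitres.  The cohort is
exchanged as a single UTF-8 comma-separated file with a header row, ``.``
decimal separator and the empty string as the missing-value token.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Neuropsychological test battery recorded per subject (missing allowed;
#: downstream analyses are complete-case / pairwise-complete).
NEUROPSYCH_TESTS: tuple[str, ...] = (
    "rcft_immediate",
    "rcft_delayed",
    "rcft_recognition",
    "svlt",
    "cowat_animal",
    "cowat_phonemic",
    "stroop_color",
    "ideomotor_praxis",
    "kbnt",
    "sgds",
)

SHRINKS = "shrinks_with_atrophy"
EXPANDS = "expands_with_atrophy"


@dataclass(frozen=True)
class Roi:
    """A region of interest with its pathological volume direction.

    ``effect_direction`` states which tail of the volume distribution is
    abnormal: grey-matter structures shrink with atrophy, ventricles expand.
    """

    name: str
    laterality: str  # "left" | "right"
    effect_direction: str  # SHRINKS | EXPANDS

    def __post_init__(self) -> None:
        if self.effect_direction not in (SHRINKS, EXPANDS):
            raise ValueError(f"unknown effect direction {self.effect_direction!r}")


#: Default 12-region panel: hippocampi and inferior lateral ventricles plus
#: the four cortical lobes, left/right.  The panel is configurable; this
#: default covers the regions implicated in amnestic MCI volumetry.
DEFAULT_ROIS: tuple[Roi, ...] = (
    Roi("hippocampus_l", "left", SHRINKS),
    Roi("hippocampus_r", "right", SHRINKS),
    Roi("inf_lat_ventricle_l", "left", EXPANDS),
    Roi("inf_lat_ventricle_r", "right", EXPANDS),
    Roi("frontal_lobe_l", "left", SHRINKS),
    Roi("frontal_lobe_r", "right", SHRINKS),
    Roi("parietal_lobe_l", "left", SHRINKS),
    Roi("parietal_lobe_r", "right", SHRINKS),
    Roi("temporal_lobe_l", "left", SHRINKS),
    Roi("temporal_lobe_r", "right", SHRINKS),
    Roi("occipital_lobe_l", "left", SHRINKS),
    Roi("occipital_lobe_r", "right", SHRINKS),
)


class SchemaError(ValueError):
    """The file does not match the cohort schema (missing column, duplicate id)."""


class RowError(ValueError):
    """One row violates a subject-level invariant; carries row context."""

    def __init__(self, row_number: int, subject_id: str | None, message: str):
        self.row_number = row_number
        self.subject_id = subject_id
        super().__init__(f"row {row_number} (subject {subject_id!r}): {message}")


@dataclass
class SubjectRecord:
    """One participant: demographics, cognition, outcome and follow-up.

    ``converted`` and ``censored`` are mutually exclusive and exhaustive;
    censoring is administrative at 36 months for non-converters.
    """

    subject_id: str
    sex: str  # "female" | "male"
    education_years: float
    age_onset: float
    age_diagnosis: float
    age_scan: float
    kmmse: int
    cdr: float
    cdr_sob: float
    gds_stage: int
    neuropsych: dict[str, float | None] = field(default_factory=dict)
    apoe4_carrier: bool = False
    converted: bool = False
    followup_months: float = 36.0
    censored: bool = True

    def validate(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.education_years < 0:
            raise ValueError("education_years must be non-negative")
        for name in ("age_onset", "age_diagnosis", "age_scan"):
            if getattr(self, name) < 50:
                raise ValueError(f"{name} must be >= 50 years (inclusion criterion)")
        if not 0 <= self.kmmse <= 30:
            raise ValueError("kmmse must be an integer in [0, 30]")
        if self.cdr < 0:
            raise ValueError("cdr must be non-negative")
        if self.cdr_sob < 0:
            raise ValueError("cdr_sob must be non-negative")
        if not 1 <= self.gds_stage <= 7:
            raise ValueError("gds_stage must be in 1..7")
        if self.converted == self.censored:
            raise ValueError("converted and censored must be mutually exclusive")
        if not 0 < self.followup_months <= 36 + 1e-9:
            if self.censored:
                raise ValueError("censored subjects must have followup_months in (0, 36]")
            if self.followup_months <= 0:
                raise ValueError("followup_months must be positive")
        unknown = set(self.neuropsych) - set(NEUROPSYCH_TESTS)
        if unknown:
            raise ValueError(f"unknown neuropsych tests: {sorted(unknown)}")


@dataclass
class RoiVolumeTable:
    """Subjects x ROI volume matrix (mL) with ROI metadata.

    ``volumes`` is indexed by subject_id with one column per ROI name;
    exactly 12 ROIs, strictly positive volumes, identical ROI set for all
    subjects (enforced by ``validate``).
    """

    volumes: pd.DataFrame
    rois: tuple[Roi, ...] = DEFAULT_ROIS

    def __post_init__(self) -> None:
        self.volumes = self.volumes.astype(float)

    @property
    def roi_names(self) -> list[str]:
        return [r.name for r in self.rois]

    def roi(self, name: str) -> Roi:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def validate(self) -> None:
        if len(self.rois) != 12:
            raise ValueError(f"expected exactly 12 ROIs, got {len(self.rois)}")
        if list(self.volumes.columns) != self.roi_names:
            raise ValueError("volume columns do not match the ROI panel")
        if len(self.volumes) and not (self.volumes.to_numpy() > 0).all():
            raise ValueError("all ROI volumes must be strictly positive")


@dataclass
class CohortLabels:
    """CU/CI partition of subject ids used for weight derivation."""

    cu: frozenset[str]
    ci: frozenset[str]

    def __post_init__(self) -> None:
        if self.cu & self.ci:
            raise ValueError("CU and CI groups must be disjoint")


_BASE_COLUMNS = (
    "subject_id",
    "sex",
    "education_years",
    "age_onset",
    "age_diagnosis",
    "age_scan",
    "kmmse",
    "cdr",
    "cdr_sob",
    "gds_stage",
    "apoe4_carrier",
    "converted",
    "followup_months",
    "censored",
)


def cohort_columns(rois: Sequence[Roi] = DEFAULT_ROIS) -> list[str]:
    """Canonical column order of the cohort CSV."""
    return (
        list(_BASE_COLUMNS)
        + [f"np_{t}" for t in NEUROPSYCH_TESTS]
        + [f"vol_{r.name}" for r in rois]
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def _parse_bool(token: str, column: str) -> bool:
    if token in ("true", "True", "1"):
        return True
    if token in ("false", "False", "0"):
        return False
    raise ValueError(f"column {column}: not a boolean: {token!r}")


def write_cohort(
    records: Iterable[SubjectRecord],
    volumes: RoiVolumeTable,
    path: str | Path,
) -> None:
    """Write the cohort to ``path`` in the canonical column order.

    Deterministic: the same cohort always produces byte-identical output, and
    ``read_cohort`` recovers every field exactly (floats are written with
    their shortest round-trip representation).
    """
    records = list(records)
    for rec in records:
        rec.validate()
    volumes.validate()
    cols = cohort_columns(volumes.rois)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for rec in records:
        row = [
            rec.subject_id,
            rec.sex,
            _fmt(float(rec.education_years)),
            _fmt(float(rec.age_onset)),
            _fmt(float(rec.age_diagnosis)),
            _fmt(float(rec.age_scan)),
            str(int(rec.kmmse)),
            _fmt(float(rec.cdr)),
            _fmt(float(rec.cdr_sob)),
            str(int(rec.gds_stage)),
            _fmt(rec.apoe4_carrier),
            _fmt(rec.converted),
            _fmt(float(rec.followup_months)),
            _fmt(rec.censored),
        ]
        for t in NEUROPSYCH_TESTS:
            v = rec.neuropsych.get(t)
            row.append("" if v is None else _fmt(float(v)))
        if rec.subject_id not in volumes.volumes.index:
            raise SchemaError(f"no volume row for subject {rec.subject_id!r}")
        vrow = volumes.volumes.loc[rec.subject_id]
        row.extend(_fmt(float(vrow[r.name])) for r in volumes.rois)
        writer.writerow(row)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cohort(
    path: str | Path,
    rois: Sequence[Roi] = DEFAULT_ROIS,
    strict: bool = True,
) -> tuple[list[SubjectRecord], RoiVolumeTable, list[RowError]]:
    """Read and validate a cohort CSV.

    Returns ``(records, volume_table, errors)``.  With ``strict=True`` (the
    default) the first invalid row raises; with ``strict=False`` invalid rows
    are collected into the error report and excluded from the returned cohort
    — they are never silently dropped.  Missing ROI volumes exclude the
    subject from the volume table (hence from brain-age scoring) but keep the
    clinical record, mirroring exclusion of technically unusable scans.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("empty file: header row required")
    expected = cohort_columns(rois)
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    idx = {c: header.index(c) for c in expected}

    records: list[SubjectRecord] = []
    vol_rows: dict[str, list[float]] = {}
    errors: list[RowError] = []
    seen: set[str] = set()
    for rownum, row in enumerate(reader, start=2):
        if not row or all(cell == "" for cell in row):
            continue
        sid = row[idx["subject_id"]]
        try:
            if sid in seen:
                raise SchemaError(f"duplicate subject_id {sid!r}")
            seen.add(sid)
            rec = _parse_row(row, idx, sid)
            rec.validate()
            vols, has_all = [], True
            for r in rois:
                tok = row[idx[f"vol_{r.name}"]]
                if tok == "":
                    has_all = False
                    break
                try:
                    vols.append(float(tok))
                except ValueError:
                    raise RowError(rownum, sid, f"non-numeric volume for {r.name}: {tok!r}")
            records.append(rec)
            if has_all:
                vol_rows[sid] = vols
        except RowError as err:
            if strict:
                raise
            errors.append(err)
        except (ValueError, SchemaError) as err:
            err2 = RowError(rownum, sid, str(err))
            if strict:
                raise err2 from err
            errors.append(err2)

    vol_df = pd.DataFrame.from_dict(
        vol_rows, orient="index", columns=[r.name for r in rois]
    )
    vol_df.index.name = "subject_id"
    table = RoiVolumeTable(vol_df, tuple(rois))
    if len(table.volumes):
        table.validate()
    return records, table, errors


def _parse_row(row: list[str], idx: Mapping[str, int], sid: str) -> SubjectRecord:
    def f(col: str) -> float:
        tok = row[idx[col]]
        try:
            return float(tok)
        except ValueError:
            raise ValueError(f"column {col}: not numeric: {tok!r}")

    neuropsych: dict[str, float | None] = {}
    for t in NEUROPSYCH_TESTS:
        tok = row[idx[f"np_{t}"]]
        neuropsych[t] = None if tok == "" else float(tok)
    return SubjectRecord(
        subject_id=sid,
        sex=row[idx["sex"]],
        education_years=f("education_years"),
        age_onset=f("age_onset"),
        age_diagnosis=f("age_diagnosis"),
        age_scan=f("age_scan"),
        kmmse=int(f("kmmse")),
        cdr=f("cdr"),
        cdr_sob=f("cdr_sob"),
        gds_stage=int(f("gds_stage")),
        neuropsych=neuropsych,
        apoe4_carrier=_parse_bool(row[idx["apoe4_carrier"]], "apoe4_carrier"),
        converted=_parse_bool(row[idx["converted"]], "converted"),
        followup_months=f("followup_months"),
        censored=_parse_bool(row[idx["censored"]], "censored"),
    )


def records_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into a DataFrame indexed by subject_id."""
    rows = []
    for rec in records:
        d = {
            "sex": rec.sex,
            "education_years": rec.education_years,
            "age_onset": rec.age_onset,
            "age_diagnosis": rec.age_diagnosis,
            "age_scan": rec.age_scan,
            "kmmse": rec.kmmse,
            "cdr": rec.cdr,
            "cdr_sob": rec.cdr_sob,
            "gds_stage": rec.gds_stage,
            "apoe4_carrier": rec.apoe4_carrier,
            "converted": rec.converted,
            "followup_months": rec.followup_months,
            "censored": rec.censored,
        }
        for t in NEUROPSYCH_TESTS:
            d[t] = rec.neuropsych.get(t)
        rows.append(pd.Series(d, name=rec.subject_id))
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration (ROI list, theta, percentile, seed...)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("run configuration must be a mapping")
    return cfg
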