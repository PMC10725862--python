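"""Age/sex normative adjustment of regional brain volumes.

Regional volumes decline (or, for ventricles, grow) with age and differ by
sex, so a raw volume is meaningless without a reference.  This module fits,
per (ROI, sex) stratum of a cognitively unimpaired reference sample, a linear
volume-on-age regression; a subject's volume is then expressed as a
standardized residual z = (observed - predicted(age)) / residual SD and as a
percentile rank of that residual within the stored reference residuals.  The
"bottom 5 percentile" atrophy boundary lives on this adjusted scale, which
makes the atrophy rule age- and sex-fair.

The mid-rank convention rank/(n+1) is used for percentiles, so ranks never
reach 0 or 1; quantile thresholds use linear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import Roi, RoiVolumeTable, SHRINKS

MIN_STRATUM = 10


class DegenerateModelError(ValueError):
    """Reference volumes carry no residual variance in some stratum."""


class MissingStratumError(KeyError):
    """A (ROI, sex) stratum requested for scoring was absent at fit time."""


@dataclass
class StratumFit:
    """Linear age fit and residual distribution for one (ROI, sex) stratum."""

    intercept: float  # mL at age 0 (extrapolated)
    slope: float  # mL / year
    resid_sd: float  # mL, sqrt(SS_res / (n - 2))
    residuals: np.ndarray  # standardized reference residuals, sorted ascending

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age


@dataclass
class NormativeModel:
    """Per-(ROI, sex) normative fits plus atrophy thresholds.

    ``atrophy_threshold`` maps each stratum to the boundary of the abnormal
    tail on the standardized-residual scale: the empirical 5th percentile for
    shrinking structures, the 95th for expanding ones (linear-interpolation
    quantile over the stored residuals).
    """

    strata: dict[tuple[str, str], StratumFit]
    atrophy_threshold: dict[tuple[str, str], float]
    atrophy_percentile: float
    rois: tuple[Roi, ...]

    def stratum(self, roi: str, sex: str) -> StratumFit:
        try:
            return self.strata[(roi, sex)]
        except KeyError:
            raise MissingStratumError(
                f"no normative stratum for ROI {roi!r}, sex {sex!r}"
            ) from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "atrophy_percentile": self.atrophy_percentile,
            "rois": [
                {"name": r.name, "laterality": r.laterality, "effect_direction": r.effect_direction}
                for r in self.rois
            ],
            "strata": [
                {
                    "roi": roi,
                    "sex": sex,
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "resid_sd": fit.resid_sd,
                    "residuals": fit.residuals.tolist(),
                    "atrophy_threshold": self.atrophy_threshold[(roi, sex)],
                }
                for (roi, sex), fit in sorted(self.strata.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        rois = tuple(
            Roi(r["name"], r["laterality"], r["effect_direction"]) for r in payload["rois"]
        )
        strata, thresholds = {}, {}
        for s in payload["strata"]:
            key = (s["roi"], s["sex"])
            strata[key] = StratumFit(
                s["intercept"], s["slope"], s["resid_sd"], np.asarray(s["residuals"])
            )
            thresholds[key] = s["atrophy_threshold"]
        return cls(strata, thresholds, payload["atrophy_percentile"], rois)


def fit_normative(
    volumes: RoiVolumeTable,
    ages: pd.Series,
    sexes: pd.Series,
    atrophy_percentile: float = 0.05,
) -> NormativeModel:
    """Fit the normative model on a cognitively unimpaired reference sample.

    ``ages`` and ``sexes`` are indexed by subject_id and must cover every
    subject in ``volumes``.  Each sex stratum needs at least ``MIN_STRATUM``
    subjects; constant volumes within a stratum raise
    :class:`DegenerateModelError`.
    """
    if not 0 < atrophy_percentile < 0.5:
        raise ValueError("atrophy_percentile must lie in (0, 0.5)")
    volumes.validate()
    ids = volumes.volumes.index
    ages = ages.loc[ids].astype(float)
    sexes = sexes.loc[ids]

    strata: dict[tuple[str, str], StratumFit] = {}
    thresholds: dict[tuple[str, str], float] = {}
    for sex in sorted(sexes.unique()):
        mask = (sexes == sex).to_numpy()
        n = int(mask.sum())
        if n < MIN_STRATUM:
            raise ValueError(
                f"reference stratum sex={sex!r} has {n} subjects; need >= {MIN_STRATUM}"
            )
        age = ages.to_numpy()[mask]
        for roi in volumes.rois:
            v = volumes.volumes[roi.name].to_numpy()[mask]
            slope, intercept = np.polyfit(age, v, 1)
            resid = v - (intercept + slope * age)
            ss = float(np.sum(resid**2))
            sd = float(np.sqrt(ss / (n - 2)))
            if sd <= 0 or not np.isfinite(sd):
                raise DegenerateModelError(
                    f"zero residual variance in stratum (roi={roi.name}, sex={sex})"
                )
            z = np.sort(resid / sd)
            q = atrophy_percentile if roi.effect_direction == SHRINKS else 1 - atrophy_percentile
            thr = float(np.quantile(z, q))
            key = (roi.name, sex)
            strata[key] = StratumFit(float(intercept), float(slope), sd, z)
            thresholds[key] = thr
    return NormativeModel(strata, thresholds, atrophy_percentile, volumes.rois)


def midrank_percentile(z: float, reference: np.ndarray) -> float:
    """Mid-rank percentile of ``z`` within sorted ``reference``: rank/(n+1).

    rank = #(ref < z) + (#(ref == z) + 1) / 2, so a value tied with the
    smallest of 99 reference points gets 1/100 and percentiles never hit
    exactly 0 or 1.
    """
    n = reference.size
    lo = int(np.searchsorted(reference, z, side="left"))
    hi = int(np.searchsorted(reference, z, side="right"))
    rank = lo + (hi - lo + 1) / 2.0
    return rank / (n + 1)


def adjust_volume(
    volume: float,
    age: float,
    sex: str,
    roi: str,
    model: NormativeModel,
) -> tuple[float, float]:
    """Adjust one volume for age and sex: returns (z, percentile in (0, 1))."""
    fit = model.stratum(roi, sex)
    z = (volume - fit.predict(age)) / fit.resid_sd
    return z, midrank_percentile(z, fit.residuals)


def adjust_table(
    volumes: RoiVolumeTable,
    ages: pd.Series,
    sexes: pd.Series,
    model: NormativeModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust a whole cohort; returns (z, pct) DataFrames, subjects x ROIs."""
    ids = volumes.volumes.index
    zs = pd.DataFrame(index=ids, columns=volumes.roi_names, dtype=float)
    ps = pd.DataFrame(index=ids, columns=volumes.roi_names, dtype=float)
    for sid in ids:
        age, sex = float(ages.loc[sid]), sexes.loc[sid]
        for roi in volumes.roi_names:
            z, p = adjust_volume(float(volumes.volumes.at[sid, roi]), age, sex, roi, model)
            zs.at[sid, roi] = z
            ps.at[sid, roi] = p
    return zs, ps
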