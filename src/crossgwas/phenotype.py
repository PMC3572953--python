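"""Airway-responsiveness slope phenotype from dose-response readings.

Each animal's phenotype is the ordinary least-squares slope of respiratory
resistance on log10(methacholine dose, mg/ml), fitted over the nonzero-dose
readings only; saline (dose 0) and baseline rows are acquired but excluded
from the fit.  Strain summaries are the mean and SEM of per-animal slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InsufficientDataError, ValidationError

LOG10_OF_E_CONVERSION = np.log(10.0)  # slope(base e) = slope(base 10) * ln(10)

DOSE_RESPONSE_COLUMNS = ["strain", "sex", "animal_id", "dose_mg_ml", "resistance"]

__all__ = [
    "DoseResponseRecord",
    "StrainSummary",
    "fit_animal_slope",
    "animal_slopes",
    "summarize_strains",
    "fold_change",
]


@dataclass(frozen=True)
class DoseResponseRecord:
    strain: str
    sex: str
    animal_id: str
    dose_mg_ml: float
    resistance: float

    def __post_init__(self) -> None:
        if self.dose_mg_ml < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose_mg_ml}")
        if self.resistance <= 0:
            raise ValidationError(f"resistance must be > 0, got {self.resistance}")


@dataclass(frozen=True)
class StrainSummary:
    """Per-strain slope mean with SEM = sample SD of animal slopes / sqrt(n)."""

    strain: str
    slope_mean: float
    slope_sem: float  # nan when only one animal
    n_animals: int


def fit_animal_slope(dose_mg_ml, resistance) -> float:
    """OLS slope of resistance on log10(dose) over nonzero-dose readings.

    Rows with dose 0 (saline/baseline) are ignored.  Requires readings at
    two or more distinct nonzero doses; negative doses are rejected.
    """
    dose = np.asarray(dose_mg_ml, dtype=float)
    resist = np.asarray(resistance, dtype=float)
    if dose.shape != resist.shape:
        raise ValidationError("dose and resistance must have equal length")
    if np.any(dose < 0):
        raise ValidationError("negative methacholine dose encountered")
    keep = dose > 0
    dose, resist = dose[keep], resist[keep]
    if np.unique(dose).size < 2:
        raise InsufficientDataError(
            f"need readings at >=2 distinct nonzero doses, got {np.unique(dose).size}"
        )
    result = linregress(np.log10(dose), resist)
    return float(result.slope)


def animal_slopes(dose_response: pd.DataFrame) -> pd.DataFrame:
    """Fit one slope per animal from a long-format dose-response table.

    Expects columns ``strain sex animal_id dose_mg_ml resistance``; returns
    a frame with one row per animal and columns ``strain sex animal_id slope``.
    """
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in dose_response.columns]
    if missing:
        raise ValidationError(f"dose-response table missing columns: {missing}")
    rows = []
    for (strain, sex, animal), grp in dose_response.groupby(
        ["strain", "sex", "animal_id"], sort=True
    ):
        slope = fit_animal_slope(grp["dose_mg_ml"], grp["resistance"])
        rows.append({"strain": strain, "sex": sex, "animal_id": animal, "slope": slope})
    return pd.DataFrame(rows)


def summarize_strains(
    slopes: pd.DataFrame, *, sex: str | None = None
) -> list[StrainSummary]:
    """Mean and SEM of per-animal slopes per strain, pooling sexes by default.

    Empty groups (e.g. after the optional sex filter) are skipped with a
    warning.  With a single animal the SEM is undefined and reported as nan.
    """
    if sex is not None:
        subset = slopes[slopes["sex"] == sex]
    else:
        subset = slopes
    summaries: list[StrainSummary] = []
    for strain in pd.unique(slopes["strain"]):
        vals = subset.loc[subset["strain"] == strain, "slope"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"strain {strain!r} has no animals after filtering; skipped")
            continue
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        summaries.append(
            StrainSummary(strain=str(strain), slope_mean=mean, slope_sem=sem,
                          n_animals=int(vals.size))
        )
    return summaries


def fold_change(summaries: list[StrainSummary]) -> float:
    """Ratio of the largest to the smallest strain mean slope."""
    if not summaries:
        raise ValidationError("no strain summaries supplied")
    means = np.array([s.slope_mean for s in summaries], dtype=float)
    if np.any(means <= 0):
        raise ValidationError("fold change undefined: nonpositive strain mean slope")
    return float(means.max() / means.min())
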