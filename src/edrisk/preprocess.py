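"""Normalisation of raw presentation records.

Three concerns, applied in flowchart order before any analysis stage:
dropping records without a usable primary diagnosis and imputing trivially
missing demographics/vitals; categorising the comorbidity score and vital
signs with the standard clinical cutoffs; and excluding low-frequency
diagnosis codes.

Cutoff conventions: written ranges are inclusive at both ends (systolic BP
90-130 mm Hg, pulse 60-90 bpm, temperature 35.5-37.5 °C are all "normal");
the abnormal categories use strict inequalities outside those ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

__all__ = [
    "CCI_CATEGORIES",
    "FilterReport",
    "ImputationLog",
    "categorize_cci",
    "categorize_vitals",
    "categorize_records",
    "impute_missing",
    "filter_low_frequency_codes",
]

CCI_CATEGORIES = ("none", "mild", "moderate", "severe")

#: Physiologic plausibility bounds (inclusive) used to validate vitals before
#: categorisation; configurable per call.
PLAUSIBLE_BOUNDS = {
    "sbp": (40.0, 300.0),
    "pulse": (20.0, 250.0),
    "temp": (30.0, 45.0),
}

_NUMERIC_IMPUTABLE = ["age", "sbp", "pulse", "temp"]
_CATEGORICAL_IMPUTABLE = ["sex", "ethnicity"]


def categorize_cci(score: int) -> str:
    """Charlson Comorbidity Index category: 0 none, 1-2 mild, 3-4 moderate, >=5 severe."""
    if score < 0:
        raise ValidationError(f"CCI score must be nonnegative, got {score}")
    if score == 0:
        return "none"
    if score <= 2:
        return "mild"
    if score <= 4:
        return "moderate"
    return "severe"


def categorize_vitals(sbp: float, pulse: float, temp: float,
                      bounds: dict | None = None) -> tuple[str, str, str]:
    """Categorise one presentation's vital signs.

    Returns ``(sbp_cat, pulse_cat, temp_cat)`` with hypotension <90 /
    hypertension >130 mm Hg, bradycardia <60 / tachycardia >90 bpm,
    hypothermia <35.5 / hyperthermia >37.5 °C; boundary values are "normal".
    """
    bounds = bounds or PLAUSIBLE_BOUNDS
    for name, value in (("sbp", sbp), ("pulse", pulse), ("temp", temp)):
        lo, hi = bounds[name]
        if not (lo <= value <= hi):
            raise ValidationError(
                f"{name}={value} outside plausible range [{lo}, {hi}]"
            )
    sbp_cat = "hypotension" if sbp < 90 else ("hypertension" if sbp > 130 else "normal")
    pulse_cat = "bradycardia" if pulse < 60 else ("tachycardia" if pulse > 90 else "normal")
    temp_cat = "hypothermia" if temp < 35.5 else ("hyperthermia" if temp > 37.5 else "normal")
    return sbp_cat, pulse_cat, temp_cat


def categorize_records(records: pd.DataFrame, bounds: dict | None = None) -> pd.DataFrame:
    """Vectorised categorisation; adds sbp_cat, pulse_cat, temp_cat, cci_cat columns."""
    bounds = bounds or PLAUSIBLE_BOUNDS
    df = records.copy()
    for name in ("sbp", "pulse", "temp"):
        lo, hi = bounds[name]
        vals = df[name].to_numpy(dtype=float)
        bad = (vals < lo) | (vals > hi) | np.isnan(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {row}: {name}={vals[row]} outside plausible range [{lo}, {hi}]"
            )
    sbp = df["sbp"].to_numpy(dtype=float)
    pulse = df["pulse"].to_numpy(dtype=float)
    temp = df["temp"].to_numpy(dtype=float)
    df["sbp_cat"] = np.select([sbp < 90, sbp > 130], ["hypotension", "hypertension"], "normal")
    df["pulse_cat"] = np.select([pulse < 60, pulse > 90], ["bradycardia", "tachycardia"], "normal")
    df["temp_cat"] = np.select([temp < 35.5, temp > 37.5], ["hypothermia", "hyperthermia"], "normal")
    cci = df["cci"].to_numpy(dtype=float)
    if (cci < 0).any():
        raise ValidationError("negative CCI score")
    df["cci_cat"] = np.select(
        [cci == 0, cci <= 2, cci <= 4], ["none", "mild", "moderate"], "severe"
    )
    return df


@dataclass
class ImputationLog:
    """Record of every imputed cell and every dropped record."""

    imputed: list[dict] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"imputed": self.imputed, "dropped": self.dropped}


def impute_missing(records: pd.DataFrame,
                   numeric_strategy: str = "median",
                   categorical_strategy: str = "mode") -> tuple[pd.DataFrame, ImputationLog]:
    """Resolve missing fields.

    Records missing the primary diagnosis code or the admission outcome are
    dropped (reason "no primary diagnosis") and listed in the log. Remaining
    missing vitals/age are filled with the column mean or median, and missing
    sex/ethnicity with the modal category; the log lists each imputed cell
    with its fill value. Non-missing values are never altered.
    """
    if numeric_strategy not in ("mean", "median"):
        raise ValueError(f"numeric_strategy must be 'mean' or 'median', got {numeric_strategy!r}")
    if categorical_strategy != "mode":
        raise ValueError(f"categorical_strategy must be 'mode', got {categorical_strategy!r}")

    log = ImputationLog()
    df = records.copy()

    unusable = df["icd10"].isna() | df["admitted"].isna()
    for row_id in df.loc[unusable, "id"]:
        log.dropped.append({"id": str(row_id), "reason": "no primary diagnosis"})
    df = df.loc[~unusable].copy()
    if df["admitted"].dtype != int:
        df["admitted"] = df["admitted"].astype(int)

    for col in _NUMERIC_IMPUTABLE:
        miss = df[col].isna()
        if not miss.any():
            continue
        observed = df.loc[~miss, col].astype(float)
        fill = float(observed.mean() if numeric_strategy == "mean" else observed.median())
        for row_id in df.loc[miss, "id"]:
            log.imputed.append({"id": str(row_id), "column": col, "value": fill})
        df.loc[miss, col] = fill

    for col in _CATEGORICAL_IMPUTABLE:
        miss = df[col].isna()
        if not miss.any():
            continue
        # pandas mode() sorts values; ties resolve alphabetically.
        fill = df.loc[~miss, col].mode().iloc[0]
        for row_id in df.loc[miss, "id"]:
            log.imputed.append({"id": str(row_id), "column": col, "value": fill})
        df.loc[miss, col] = fill

    return df, log


@dataclass(frozen=True)
class FilterReport:
    """Accounting for the low-frequency code exclusion."""

    min_count: int
    n_records_in: int
    n_records_kept: int
    n_records_excluded: int
    excluded_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.n_records_kept + self.n_records_excluded == self.n_records_in

    def to_dict(self) -> dict:
        return {
            "min_count": self.min_count,
            "n_records_in": self.n_records_in,
            "n_records_kept": self.n_records_kept,
            "n_records_excluded": self.n_records_excluded,
            "excluded_codes": list(self.excluded_codes),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def filter_low_frequency_codes(records: pd.DataFrame,
                               min_count: int = 15) -> tuple[pd.DataFrame, FilterReport]:
    """Exclude ICD-10 codes with fewer than ``min_count`` presentations.

    Rare codes produce unstable risk estimates that behave as outliers in the
    clustering; the default threshold of 15 keeps the excluded records a
    sub-percent fraction of a registry at scale (10 is the conventional
    sensitivity value). Idempotent at a fixed threshold.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = records["icd10"].value_counts()
    excluded = counts[counts < min_count]
    keep = ~records["icd10"].isin(excluded.index)
    kept = records.loc[keep].copy()
    report = FilterReport(
        min_count=min_count,
        n_records_in=len(records),
        n_records_kept=len(kept),
        n_records_excluded=int(len(records) - len(kept)),
        excluded_codes=tuple(sorted(excluded.index)),
    )
    return kept, report
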