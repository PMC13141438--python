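"""Corticosteroid dose handling: prednisolone-equivalent conversion, 24-hour
binning, cumulative window doses and threshold-based exposure classification.

All systemic corticosteroid administrations (oral or intravenous) are assumed
to have been recorded in 24-hour bins indexed in days from ARDS onset (day 0).
Doses are rescaled to prednisolone-equivalent (PE) milligrams with a standard
potency table and accumulated over 3-day windows.  A window is *treated* at a
threshold when the cumulative PE dose reaches the threshold (closed lower
bound), *control* when it is exactly zero, and *excluded* otherwise — the
intermediate band is dropped so every contrast is 0 mg versus >=threshold mg.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Multiplicative factors drug-mg -> prednisolone-equivalent mg.
#: Anchors: 5 mg prednisolone == 5 mg prednisone == 20 mg hydrocortisone
#: == 4 mg methylprednisolone == 0.75 mg dexamethasone.
DEFAULT_EQUIVALENCE: dict[str, float] = {
    "prednisolone": 1.0,
    "prednisone": 1.0,
    "hydrocortisone": 0.25,
    "methylprednisolone": 1.25,
    "dexamethasone": 5.0 / 0.75,
}

#: Cumulative 3-day PE thresholds (mg) examined in the primary analysis.
THRESHOLDS_MG: tuple[float, ...] = (30.0, 150.0, 270.0, 390.0)

#: Any single-window cumulative dose above this marks pulse-dose steroids.
PULSE_DOSE_MG: float = 1000.0

DOSE_COLUMNS = ("patient_id", "day_bin", "drug", "dose_mg", "route")


class Exposure(str, enum.Enum):
    CONTROL = "control"
    TREATED = "treated"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ExposureLabel:
    """Window exposure class together with the cumulative window PE dose."""

    status: Exposure
    window_pe_mg: float


class UnknownDrugError(KeyError):
    pass


def to_pe(drug: str, dose_mg: float, table: Mapping[str, float] | None = None) -> float:
    """Convert a single administration to prednisolone-equivalent mg.

    Exact arithmetic contract: ``dose_mg * factor``, no rounding.  Unknown
    drugs raise (never silently contribute zero).
    """
    table = DEFAULT_EQUIVALENCE if table is None else table
    key = str(drug).strip().lower()
    if key not in table:
        raise UnknownDrugError(
            f"unknown corticosteroid {drug!r}; known drugs: {sorted(table)}"
        )
    if dose_mg < 0:
        raise ValueError(f"negative dose {dose_mg} mg for {drug}")
    return float(dose_mg) * float(table[key])


def add_pe_column(doses: pd.DataFrame, table: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Return a copy of a dose-event table with a ``pe_mg`` column appended."""
    table = DEFAULT_EQUIVALENCE if table is None else table
    out = doses.copy()
    if len(out) == 0:
        out["pe_mg"] = np.asarray([], dtype=float)
        return out
    drugs = out["drug"].astype(str).str.strip().str.lower()
    unknown = set(drugs) - set(table)
    if unknown:
        raise UnknownDrugError(
            f"unknown corticosteroid(s) {sorted(unknown)}; known drugs: {sorted(table)}"
        )
    factors = drugs.map(table).astype(float)
    if (out["dose_mg"].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative dose_mg in dose-event table")
    out["pe_mg"] = out["dose_mg"].to_numpy(dtype=float) * factors.to_numpy()
    return out


def window_dose(
    doses: pd.DataFrame,
    patient_id: object,
    window: tuple[int, int],
    table: Mapping[str, float] | None = None,
) -> float:
    """Cumulative PE dose (mg) for one patient over a 3-day window.

    ``window`` is the inclusive ``(start_day, end_day)`` pair of 24-h bins;
    events outside it contribute nothing; no events -> 0.0.
    """
    start, end = int(window[0]), int(window[1])
    if end - start != 2:
        raise ValueError(f"window {window} is not 3 consecutive day-bins")
    sub = doses[doses["patient_id"] == patient_id]
    sub = sub[(sub["day_bin"] >= start) & (sub["day_bin"] <= end)]
    if len(sub) == 0:
        return 0.0
    return float(add_pe_column(sub, table)["pe_mg"].sum())


def window_dose_table(
    doses: pd.DataFrame,
    window: tuple[int, int],
    patient_ids: Iterable[object],
    table: Mapping[str, float] | None = None,
) -> pd.Series:
    """Vectorised ``window_dose`` over many patients (missing patients -> 0)."""
    start, end = int(window[0]), int(window[1])
    if end - start != 2:
        raise ValueError(f"window {window} is not 3 consecutive day-bins")
    index = pd.Index(list(patient_ids), name="patient_id")
    sub = doses[(doses["day_bin"] >= start) & (doses["day_bin"] <= end)]
    if len(sub) == 0:
        return pd.Series(0.0, index=index)
    totals = add_pe_column(sub, table).groupby("patient_id")["pe_mg"].sum()
    return totals.reindex(index, fill_value=0.0).astype(float)


def classify_exposure(pe_mg: float, threshold: float) -> ExposureLabel:
    """Classify a cumulative window PE dose against a threshold.

    control <=> dose == 0; treated <=> dose >= threshold (closed bound, so a
    dose exactly at the threshold is treated); excluded <=> 0 < dose <
    threshold (the intermediate band dropped from that contrast, which also
    realises the physiologic-replacement exclusion at the 30 mg tier).
    """
    if pe_mg < 0:
        raise ValueError(f"negative cumulative dose {pe_mg}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if pe_mg == 0:
        return ExposureLabel(Exposure.CONTROL, 0.0)
    if pe_mg >= threshold:
        return ExposureLabel(Exposure.TREATED, float(pe_mg))
    return ExposureLabel(Exposure.EXCLUDED, float(pe_mg))


#: Pre-ARDS cumulative-PE bands of the cohort-characteristics table.
PRE_ARDS_BANDS = ("none", "<45", "45-<120", ">120")


def pre_ards_exposure_category(
    doses: pd.DataFrame,
    patient_id: object,
    table: Mapping[str, float] | None = None,
) -> str:
    """Band the cumulative PE dose over the 72 h before ARDS onset.

    Day-bins -3..-1 count.  Bands: none (0), <45, 45-<120, >120 mg; a dose of
    exactly 120 mg goes to the top band.
    """
    sub = doses[doses["patient_id"] == patient_id]
    sub = sub[(sub["day_bin"] >= -3) & (sub["day_bin"] <= -1)]
    total = float(add_pe_column(sub, table)["pe_mg"].sum()) if len(sub) else 0.0
    return _band_pre_ards(total)


def _band_pre_ards(total: float) -> str:
    if total == 0:
        return "none"
    if total < 45:
        return "<45"
    if total < 120:
        return "45-<120"
    return ">120"


def pre_ards_category_table(
    doses: pd.DataFrame,
    patient_ids: Iterable[object],
    table: Mapping[str, float] | None = None,
) -> pd.Series:
    """Vectorised pre-ARDS banding over many patients."""
    index = pd.Index(list(patient_ids), name="patient_id")
    sub = doses[(doses["day_bin"] >= -3) & (doses["day_bin"] <= -1)]
    if len(sub) == 0:
        totals = pd.Series(0.0, index=index)
    else:
        totals = (
            add_pe_column(sub, table)
            .groupby("patient_id")["pe_mg"]
            .sum()
            .reindex(index, fill_value=0.0)
        )
    return totals.map(_band_pre_ards)


def pulse_dose_patients(
    doses: pd.DataFrame,
    windows: Iterable[tuple[int, int]],
    table: Mapping[str, float] | None = None,
    cutoff: float = PULSE_DOSE_MG,
) -> set:
    """Patients whose cumulative PE dose exceeds ``cutoff`` in any window.

    Used by the pulse-steroid sensitivity exclusion (>1000 mg PE / 3 days).
    """
    flagged: set = set()
    ids = doses["patient_id"].unique()
    for window in windows:
        totals = window_dose_table(doses, window, ids, table)
        flagged.update(totals.index[totals > cutoff])
    return flagged


def read_dose_table(path) -> pd.DataFrame:
    """Read a delimited dose-event table, validating the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose table {path} is missing required column(s): {missing}")
    return df
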