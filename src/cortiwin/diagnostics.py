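"""Overlap and balance diagnostics (ESS, weighted SMD) and the
cohort-characteristics table.

Balance is assessed after overlap weighting with the arm-form balancing
weights (1 - e for treated rows, e for controls); with a maximum-likelihood
logistic propensity these equalise weighted covariate means between arms
exactly, which serves as a hard numerical oracle for the whole pipeline.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doses import THRESHOLDS_MG, pre_ards_category_table, window_dose_table
from .windows import Window, make_windows


def ess(weights) -> float:
    """Effective sample size (sum w)^2 / sum w^2; equals n for constant
    weights and shrinks as weights concentrate."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    s2 = float((w**2).sum())
    if s2 == 0:
        raise ValueError("all-zero weights have no effective sample size")
    return float(w.sum() ** 2 / s2)


def balancing_weights(e, A) -> np.ndarray:
    """Arm-form overlap balancing weights: 1-e for treated rows, e for
    controls (both proportional to e(1-e) over the respective arm)."""
    e = np.asarray(e, dtype=float)
    A = np.asarray(A).astype(int)
    return np.where(A == 1, 1.0 - e, e)


def weighted_smd(x, A, w) -> float:
    """Absolute standardised mean difference after weighting.

    Weighted arm means; pooled SD from *unweighted* arm variances,
    sqrt((s1^2 + s0^2)/2) — the common balance-diagnostic convention.  Binary
    covariates enter as 0/1 numerics.  Zero pooled SD with equal means is
    defined as 0; with unequal means it is incalculable (NaN).
    """
    x = np.asarray(x, dtype=float)
    A = np.asarray(A).astype(int)
    w = np.asarray(w, dtype=float)
    if (A == 1).sum() == 0 or (A == 0).sum() == 0:
        raise ValueError("both arms must be present")
    m1 = np.average(x[A == 1], weights=w[A == 1])
    m0 = np.average(x[A == 0], weights=w[A == 0])
    s1 = x[A == 1].std(ddof=1) if (A == 1).sum() > 1 else 0.0
    s0 = x[A == 0].std(ddof=1) if (A == 0).sum() > 1 else 0.0
    pooled = np.sqrt((s1**2 + s0**2) / 2.0)
    if pooled == 0:
        return 0.0 if np.isclose(m1, m0) else float("nan")
    return float(abs(m1 - m0) / pooled)


def balance_table(X, A, e, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-covariate weighted absolute SMD under overlap balancing weights."""
    X = np.asarray(X, dtype=float)
    w = balancing_weights(e, A)
    names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    rows = [{"covariate": nm, "smd": weighted_smd(X[:, j], A, w)}
            for j, nm in enumerate(names)]
    return pd.DataFrame(rows)


def balance_summary(balance: pd.DataFrame) -> pd.DataFrame:
    """Summarise a long per-covariate SMD table (columns window_label,
    threshold, smd) into median SMD and the fractions below 0.2 / 0.1."""
    def agg(g):
        return pd.Series({
            "median_smd": g["smd"].median(),
            "frac_smd_lt_02": (g["smd"] < 0.2).mean(),
            "frac_smd_lt_01": (g["smd"] < 0.1).mean(),
        })
    return (balance.groupby(["window_label", "threshold"], sort=False)
            .apply(agg, include_groups=False).reset_index())


def percentage(count: int, denom: int) -> float:
    """Table-style percentage: count / denom * 100 rounded to 1 decimal."""
    if denom == 0:
        return 0.0
    return round(100.0 * count / denom, 1)


def threshold_membership(
    doses: pd.DataFrame,
    patient_ids: Iterable,
    windows: Sequence[Window] | None = None,
    thresholds: Sequence[float] = THRESHOLDS_MG,
    equivalence: Mapping[str, float] | None = None,
) -> dict[object, set]:
    """Column membership for the cohort table: a patient belongs to a
    threshold column when their cumulative window PE dose met it in at least
    one window (so the columns nest); "none" = no in-ICU corticosteroid at
    all (day bins >= 0)."""
    windows = make_windows() if windows is None else list(windows)
    ids = list(patient_ids)
    max_dose = pd.Series(0.0, index=pd.Index(ids, name="patient_id"))
    for w in windows:
        max_dose = np.maximum(max_dose, window_dose_table(doses, w.days, ids, equivalence))
    icu_doses = doses[doses["day_bin"] >= 0]
    any_steroid = set(icu_doses.loc[icu_doses["dose_mg"] > 0, "patient_id"].unique())
    groups: dict[object, set] = {"none": set(ids) - any_steroid}
    for t in thresholds:
        groups[t] = set(max_dose.index[max_dose >= t])
    return groups


def cohort_table(
    patients: pd.DataFrame,
    doses: pd.DataFrame,
    outcomes: pd.DataFrame,
    thresholds: Sequence[float] = THRESHOLDS_MG,
    windows: Sequence[Window] | None = None,
) -> pd.DataFrame:
    """Baseline-characteristics table by corticosteroid dose subgroup.

    Columns: overall, no corticosteroids, and one per threshold ("met in at
    least one window", nested).  Binary rows are "n (pct)", continuous rows
    "median (q1-q3)".
    """
    ids = patients["patient_id"].tolist()
    groups = threshold_membership(doses, ids, windows, thresholds)
    columns = {"overall": set(ids), "none": groups["none"],
               **{f">={t:g}": groups[t] for t in thresholds}}
    pt = patients.set_index("patient_id")
    out = outcomes.set_index("patient_id")
    pre_cat = pre_ards_category_table(doses, ids)

    binary_rows = {"hospital_mortality": out["hospital_mortality"].astype(int)}
    binary_rows["male"] = pt["male"].astype(int)
    for c in ("ihd", "heart_failure", "chronic_lung", "ckd", "liver_disease",
              "diabetes", "cancer"):
        if c in pt.columns:
            binary_rows[c] = pt[c].astype(int)
    for band in ("<45", "45-<120", ">120"):
        binary_rows[f"pre_ards_{band}"] = (pre_cat == band).astype(int)

    table: dict[str, dict[str, str]] = {}
    for col, members in columns.items():
        members = pd.Index(sorted(members))
        N = len(members)
        cells = {"N (%)": f"{N} ({percentage(N, len(ids))})"}
        age = pt.loc[members, "age"] if N else pd.Series(dtype=float)
        if N:
            q1, med, q3 = np.percentile(age, [25, 50, 75])
            cells["age_median_iqr"] = f"{med:.0f} ({q1:.0f}-{q3:.0f})"
        else:
            cells["age_median_iqr"] = "-"
        for name, series in binary_rows.items():
            cnt = int(series.reindex(members).fillna(0).sum()) if N else 0
            cells[name] = f"{cnt} ({percentage(cnt, N)})"
        table[col] = cells
    return pd.DataFrame(table)
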