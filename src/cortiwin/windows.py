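"""Landmark sliding windows: the 13 overlapping 3-day windows after ARDS
onset, per-window patient eligibility, LOCF pre-filling of laboratory series,
within-window covariate summaries, and assembly of the per-window analysis
frame.

Day convention: day ``d`` covers hours ``[24*d, 24*(d+1))`` from ARDS onset
(half-open, 0-based).  A patient is eligible for a window when they are alive
and still under ICU observation through the window's end day; exposure is
assessed inside the window and follow-up begins at its end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doses import add_pe_column, pre_ards_category_table, window_dose_table

N_WINDOWS = 13
WINDOW_LENGTH_DAYS = 3
LOCF_MAX_CARRY_HOURS = 48.0

#: Variables never carried forward (arterial blood gas results).
DEFAULT_ABG_VARIABLES = frozenset({"pf_ratio", "paco2", "ph"})

DYNAMICS_COLUMNS = ("patient_id", "hour", "variable", "value", "observed")
OUTCOME_COLUMNS = ("patient_id", "death_day", "icu_discharge_day", "hospital_mortality")


@dataclass(frozen=True)
class Window:
    """One 3-day landmark window (inclusive day bins ``start..start+2``)."""

    index: int
    start: int

    @property
    def end(self) -> int:
        return self.start + WINDOW_LENGTH_DAYS - 1

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @property
    def days(self) -> tuple[int, int]:
        return (self.start, self.end)


def make_windows(n_windows: int = N_WINDOWS) -> list[Window]:
    """The overlapping windows 0-2, 1-3, ..., 12-14 (13 by default)."""
    return [Window(index=i, start=i) for i in range(n_windows)]


def eligible(outcomes: pd.DataFrame, window: Window) -> pd.Series:
    """Landmark eligibility: alive and under ICU observation through the
    window's end day.

    Patients discharged alive from ICU before the end day are ineligible for
    that and later windows; for eligible patients the outcome remains
    hospital mortality, which may occur after ICU discharge.
    """
    death = outcomes["death_day"].to_numpy(dtype=float)
    discharge = outcomes["icu_discharge_day"].to_numpy(dtype=float)
    alive_through = np.isnan(death) | (death > window.end)
    observed_through = discharge >= window.end
    return pd.Series(
        alive_through & observed_through,
        index=pd.Index(outcomes["patient_id"], name="patient_id"),
    )


def locf_fill(
    obs_hours: Sequence[float],
    obs_values: Sequence[float],
    query_hours: Sequence[float],
    max_carry_hours: float = LOCF_MAX_CARRY_HOURS,
    is_abg: bool = False,
) -> np.ndarray:
    """Last observation carried forward, capped at 48 h and disabled for ABG.

    ``obs_hours`` must be sorted; a query at an observation time returns the
    observation itself (age 0).  Queries with no observation within the carry
    limit stay NaN.
    """
    obs_hours = np.asarray(obs_hours, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    query = np.asarray(query_hours, dtype=float)
    out = np.full(query.shape, np.nan)
    if obs_hours.size == 0:
        return out
    idx = np.searchsorted(obs_hours, query, side="right") - 1
    has_prev = idx >= 0
    age = np.where(has_prev, query - obs_hours[np.clip(idx, 0, None)], np.inf)
    limit = 0.0 if is_abg else max_carry_hours
    ok = has_prev & (age <= limit)
    out[ok] = obs_values[idx[ok]]
    return out


@dataclass(frozen=True)
class DynamicSummary:
    """Mean / range / variance / last value over a window, or all-missing."""

    mean: float
    range: float
    variance: float
    last: float
    all_missing: bool


def summarize_dynamics(values: Sequence[float]) -> DynamicSummary:
    """Summaries over the observed in-window values.

    Sample variance (n-1 denominator); one observation gives range 0 and
    variance 0; zero observations set the all-missing indicator.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return DynamicSummary(np.nan, np.nan, np.nan, np.nan, True)
    variance = float(np.var(v, ddof=1)) if v.size > 1 else 0.0
    return DynamicSummary(
        mean=float(v.mean()),
        range=float(v.max() - v.min()),
        variance=variance,
        last=float(v[-1]),
        all_missing=False,
    )


class DynamicsPanel:
    """Per-variable (patient x day) matrices of daily measurements with LOCF
    pre-filling applied; built once per cohort and sliced per window."""

    def __init__(
        self,
        dynamics: pd.DataFrame,
        patient_ids: Sequence,
        horizon_days: int,
        abg_variables: Iterable[str] = DEFAULT_ABG_VARIABLES,
        max_carry_hours: float = LOCF_MAX_CARRY_HOURS,
    ):
        missing = [c for c in DYNAMICS_COLUMNS if c not in dynamics.columns]
        if missing:
            raise ValueError(f"dynamics table is missing required column(s): {missing}")
        self.patient_index = pd.Index(patient_ids, name="patient_id")
        self.horizon_days = int(horizon_days)
        self.variables = sorted(dynamics["variable"].unique())
        abg = set(abg_variables)
        obs = dynamics[dynamics["observed"].astype(bool)]
        day = (obs["hour"].to_numpy(dtype=float) // 24).astype(int)
        self.raw: dict[str, np.ndarray] = {}
        self.filled: dict[str, np.ndarray] = {}
        row_of = {pid: i for i, pid in enumerate(self.patient_index)}
        for var in self.variables:
            mat = np.full((len(self.patient_index), self.horizon_days), np.nan)
            sub = obs[obs["variable"] == var]
            rows = sub["patient_id"].map(row_of).to_numpy()
            cols = day[obs["variable"] == var]
            keep = cols < self.horizon_days
            mat[rows[keep], cols[keep]] = sub["value"].to_numpy(dtype=float)[keep]
            self.raw[var] = mat
            if var in abg or max_carry_hours <= 0:
                self.filled[var] = mat
            else:
                self.filled[var] = _locf_matrix(mat, int(max_carry_hours // 24))

    def window_summaries(self, window: Window) -> pd.DataFrame:
        """One row per patient with ``{var}_{mean,range,var,last,missing}``."""
        cols: dict[str, np.ndarray] = {}
        for var in self.variables:
            block = self.filled[var][:, window.start : window.end + 1]
            isobs = ~np.isnan(block)
            n_obs = isobs.sum(axis=1)
            safe = np.where(isobs, block, 0.0)
            mean = np.where(n_obs > 0, safe.sum(axis=1) / np.maximum(n_obs, 1), np.nan)
            hi = np.where(isobs, block, -np.inf).max(axis=1)
            lo = np.where(isobs, block, np.inf).min(axis=1)
            rng = np.where(n_obs > 0, hi - lo, np.nan)
            var_ = np.full(block.shape[0], np.nan)
            multi = n_obs > 1
            if multi.any():
                centred = np.where(isobs[multi], block[multi] - mean[multi, None], 0.0)
                var_[multi] = (centred**2).sum(axis=1) / (n_obs[multi] - 1)
            var_[n_obs == 1] = 0.0
            last = np.full(block.shape[0], np.nan)
            any_obs = n_obs > 0
            if any_obs.any():
                rev_idx = block.shape[1] - 1 - np.argmax(isobs[:, ::-1], axis=1)
                last[any_obs] = block[any_obs, rev_idx[any_obs]]
            cols[f"{var}_mean"] = mean
            cols[f"{var}_range"] = rng
            cols[f"{var}_var"] = var_
            cols[f"{var}_last"] = last
            cols[f"{var}_missing"] = (n_obs == 0).astype(float)
        return pd.DataFrame(cols, index=self.patient_index)


def _locf_matrix(mat: np.ndarray, max_carry_days: int) -> np.ndarray:
    """Daily-grid LOCF: a NaN day takes the most recent observed value at
    most ``max_carry_days`` days back (48 h cap -> 2 days on a daily grid)."""
    out = mat.copy()
    n, t = mat.shape
    last_val = np.full(n, np.nan)
    last_age = np.full(n, np.inf)
    for d in range(t):
        col = mat[:, d]
        obs = ~np.isnan(col)
        last_val[obs] = col[obs]
        last_age[obs] = 0.0
        fill = ~obs & (last_age + 1 <= max_carry_days) & ~np.isnan(last_val)
        out[fill, d] = last_val[fill]
        last_age += 1.0
    return out


BASELINE_BINARY = (
    "male",
    "ihd",
    "heart_failure",
    "chronic_lung",
    "ckd",
    "liver_disease",
    "diabetes",
    "cancer",
)


@dataclass
class WindowFrame:
    """The per-window analysis table: one row per eligible, non-excluded
    patient with exposure, outcome and covariates."""

    window: Window
    threshold: float
    data: pd.DataFrame            # patient_id index; treated, outcome, window_pe + covariates
    covariates: list[str]
    n_excluded: int               # intermediate-dose rows dropped
    n_eligible: int               # eligible before exposure filtering

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_treated(self) -> int:
        return int(self.data["treated"].sum())

    @property
    def n_control(self) -> int:
        return int((1 - self.data["treated"]).sum())

    def degenerate(self, floor: int = 1) -> bool:
        """True when either arm has fewer than ``floor`` patients (the
        estimator must refuse such frames)."""
        return self.n_treated < floor or self.n_control < floor

    def X(self) -> pd.DataFrame:
        return self.data[self.covariates]


def assemble_frame(
    patients: pd.DataFrame,
    doses: pd.DataFrame,
    outcomes: pd.DataFrame,
    panel: DynamicsPanel,
    window: Window,
    threshold: float,
    equivalence: Mapping[str, float] | None = None,
) -> WindowFrame:
    """Join eligibility, exposure classification, covariate summaries and the
    outcome into the analysis frame for one window x threshold.

    Covariates = baseline demographics/comorbidities + pre-ARDS PE category
    (one-hot) + corticosteroid-history terms (cumulative PE from day 0 to the
    window start, any steroid in the prior 3 days) + per-variable window
    summaries.
    """
    missing = [c for c in OUTCOME_COLUMNS if c not in outcomes.columns]
    if missing:
        raise ValueError(f"outcomes table is missing required column(s): {missing}")
    elig = eligible(outcomes, window)
    ids = elig.index[elig.to_numpy()]
    n_eligible = len(ids)

    pe = window_dose_table(doses, window.days, ids, equivalence)
    treated = pe >= threshold
    control = pe == 0
    keep = treated | control
    n_excluded = int((~keep).sum())
    ids = ids[keep.to_numpy()]

    base = patients.set_index("patient_id").loc[ids]
    cov = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    cov["age"] = base["age"].astype(float)
    for col in BASELINE_BINARY:
        if col in base.columns:
            cov[col] = base[col].astype(float)

    cat = pre_ards_category_table(doses, ids, equivalence)
    for band, name in (("<45", "pre_ards_lt45"), ("45-<120", "pre_ards_45_120"), (">120", "pre_ards_gt120")):
        cov[name] = (cat == band).astype(float)

    cov["cum_pe_pre_window"] = _cumulative_pe_before(doses, ids, window.start, equivalence)
    cov["prior3d_steroid"] = _any_dose_in(doses, ids, window.start - 3, window.start - 1)

    summaries = panel.window_summaries(window).loc[ids]
    cov = cov.join(summaries)

    data = cov.copy()
    data.insert(0, "window_pe", pe[keep].to_numpy(dtype=float))
    data.insert(0, "outcome", outcomes.set_index("patient_id").loc[ids, "hospital_mortality"].astype(int).to_numpy())
    data.insert(0, "treated", treated[keep].astype(int).to_numpy())

    return WindowFrame(
        window=window,
        threshold=float(threshold),
        data=data,
        covariates=list(cov.columns),
        n_excluded=n_excluded,
        n_eligible=n_eligible,
    )


def _cumulative_pe_before(doses, ids, start_day, equivalence) -> np.ndarray:
    index = pd.Index(ids, name="patient_id")
    sub = doses[(doses["day_bin"] >= 0) & (doses["day_bin"] < start_day)]
    if len(sub) == 0:
        return np.zeros(len(index))
    totals = add_pe_column(sub, equivalence).groupby("patient_id")["pe_mg"].sum()
    return totals.reindex(index, fill_value=0.0).to_numpy(dtype=float)


def _any_dose_in(doses, ids, day_lo, day_hi) -> np.ndarray:
    index = pd.Index(ids, name="patient_id")
    sub = doses[(doses["day_bin"] >= day_lo) & (doses["day_bin"] <= day_hi)]
    flag = pd.Series(0.0, index=index)
    present = index.intersection(pd.Index(sub["patient_id"].unique()))
    flag.loc[present] = 1.0
    return flag.to_numpy()


def ards_screen(
    pf_by_day: np.ndarray,
    peep_by_day: np.ndarray,
    death_day: float | None = None,
) -> bool:
    """Optional numeric inclusion screen on a simulated trajectory: P/F < 300
    with PEEP >= 5 persisting 3 days (2 days when death occurred on day 3).

    Not part of the estimand pipeline; the simulator labels all patients as
    ARDS.
    """
    pf = np.asarray(pf_by_day, dtype=float)
    peep = np.asarray(peep_by_day, dtype=float)
    need = 2 if (death_day is not None and death_day == 3) else 3
    ok = (pf < 300) & (peep >= 5)
    ok = ok[: max(need, 0)]
    return bool(ok.size >= need and ok[:need].all())
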