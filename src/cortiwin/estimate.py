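"""Overlap-weighted AIPW risk differences per window x threshold.

The primary estimand is the overlap-weighted risk difference (OWRD): with
cross-fitted propensities e_i and outcome risks m1_i/m0_i, overlap weights
w_i = e_i (1 - e_i), and the augmented pseudo-outcome numerator

    num_i = w_i (m1_i - m0_i) + A_i (1 - e_i)(Y_i - m1_i)
                               - (1 - A_i) e_i (Y_i - m0_i),

the estimate is tau = sum(num_i) / sum(w_i).  The standard error comes from
per-row influence contributions phi_i = (num_i - tau w_i) / mean(w); a
percentile bootstrap is available as an option.  A standard (full-population)
AIPW risk difference with Hajek-stabilised weights and propensity truncation
at 0.01 / 0.05 is the sensitivity estimator.

The estimator is doubly robust: a correctly specified propensity model makes
it consistent for the overlap-population risk difference regardless of the
outcome model; a correctly specified outcome model alone makes it consistent
for the fitted-weight average of the true conditional effect, which equals
the overlap-population contrast whenever the effect is homogeneous or null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import balance_table, ess
from .doses import THRESHOLDS_MG
from .impute import mice_impute, rubin_pool
from .learners import DEFAULT_LEARNERS, LearnerSpec, NuisanceFit, crossfit_superlearner, ps_metrics
from .simulate import SimCohort
from .windows import DynamicsPanel, Window, WindowFrame, assemble_frame, make_windows

Z_975 = 1.959963984540054
DEFAULT_ARM_FLOOR = 5


class NoOverlapError(RuntimeError):
    """Raised instead of silently returning 0 when a frame has no usable
    treated/control contrast."""


@dataclass(frozen=True)
class WindowEstimate:
    """One cell of the results grid (possibly pooled over imputations)."""

    window_label: str
    threshold: float
    estimand: str           # "owrd" or "ate_trunc_<level>"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_treated: int
    n_control: int
    ess: float
    M: int = 1


def _check_arms(A):
    A = np.asarray(A).astype(int)
    if A.sum() == 0 or A.sum() == len(A):
        raise NoOverlapError(
            f"degenerate frame: n_treated={int(A.sum())}, n_control={int(len(A) - A.sum())}"
        )
    return A


def owrd(fit: NuisanceFit, A, Y, window_label: str = "", threshold: float = np.nan,
         normalization: str = "arm") -> WindowEstimate:
    """Overlap-weighted AIPW risk difference with influence-function SE.

    ``normalization="arm"`` (default) self-normalises each arm's residual
    term by its own weight sum (Hajek form), which keeps small, poorly
    overlapped cells finite; ``"pooled"`` divides the summed pseudo-outcome
    numerator by the single overlap-weight sum.  The two coincide when e is
    constant and are asymptotically equivalent in general.
    """
    A = _check_arms(A)
    Y = np.asarray(Y).astype(int)
    e, m1, m0 = fit.e, fit.m1, fit.m0
    if e is None or m1 is None or m0 is None:
        raise ValueError("fit must carry e, m1 and m0 (merge propensity and outcome fits)")
    w = e * (1.0 - e)
    if w.sum() <= 0:
        raise NoOverlapError("overlap weights sum to zero")
    d = m1 - m0
    a1 = A * (1.0 - e) * (Y - m1)
    b1 = A * (1.0 - e)
    a0 = (1 - A) * e * (Y - m0)
    b0 = (1 - A) * e
    if b1.sum() <= 0 or b0.sum() <= 0:
        raise NoOverlapError("an arm carries no overlap weight")
    if normalization == "arm":
        t_w = float(np.sum(w * d) / w.sum())
        t1 = float(a1.sum() / b1.sum())
        t0 = float(a0.sum() / b0.sum())
        tau = t_w + t1 - t0
        phi = (w * (d - t_w)) / w.mean() + (a1 - t1 * b1) / b1.mean() - (a0 - t0 * b0) / b0.mean()
    elif normalization == "pooled":
        num = w * d + a1 - a0
        tau = float(num.sum() / w.sum())
        phi = (num - tau * w) / w.mean()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    se = float(np.std(phi, ddof=1) / np.sqrt(len(phi)))
    return WindowEstimate(
        window_label=window_label, threshold=float(threshold), estimand="owrd",
        estimate=float(tau), se=se, ci_low=tau - Z_975 * se, ci_high=tau + Z_975 * se,
        n=len(A), n_treated=int(A.sum()), n_control=int(len(A) - A.sum()),
        ess=ess(w),
    )


def aipw_ate_truncated(fit: NuisanceFit, A, Y, trunc: float = 0.01,
                       window_label: str = "", threshold: float = np.nan) -> WindowEstimate:
    """Standard AIPW risk difference with Hajek-stabilised weights and
    propensity truncation (sensitivity estimator; full target population)."""
    A = _check_arms(A)
    Y = np.asarray(Y).astype(int)
    if not 0 < trunc < 0.5:
        raise ValueError(f"truncation level must be in (0, 0.5), got {trunc}")
    e = np.clip(fit.e, trunc, 1.0 - trunc)
    m1, m0 = fit.m1, fit.m0
    n = len(A)
    a1 = A * (Y - m1) / e
    b1 = A / e
    a0 = (1 - A) * (Y - m0) / (1.0 - e)
    b0 = (1 - A) / (1.0 - e)
    s1 = a1.sum() / b1.sum()
    s0 = a0.sum() / b0.sum()
    mu = float(np.mean(m1 - m0))
    tau = mu + s1 - s0
    phi = (m1 - m0 - mu) + (a1 - s1 * b1) / b1.mean() - (a0 - s0 * b0) / b0.mean()
    se = float(np.std(phi, ddof=1) / np.sqrt(n))
    return WindowEstimate(
        window_label=window_label, threshold=float(threshold),
        estimand=f"ate_trunc_{trunc:g}",
        estimate=float(tau), se=se, ci_low=tau - Z_975 * se, ci_high=tau + Z_975 * se,
        n=n, n_treated=int(A.sum()), n_control=int(n - A.sum()),
        ess=ess(e * (1 - e)),
    )


def individual_rd(fit: NuisanceFit) -> np.ndarray:
    """Per-row predicted risk difference m1(x) - m0(x), in [-1, 1]."""
    if fit.m1 is None or fit.m0 is None:
        raise ValueError("fit has no outcome predictions")
    return np.asarray(fit.m1 - fit.m0, dtype=float)


def bootstrap_ci(fit: NuisanceFit, A, Y, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap over rows of the OWRD pseudo-outcome ratio
    (nuisances held fixed); optional alternative to the influence-function CI."""
    A = _check_arms(A)
    Y = np.asarray(Y).astype(int)
    e, m1, m0 = fit.e, fit.m1, fit.m0
    w = e * (1 - e)
    num = w * (m1 - m0) + A * (1 - e) * (Y - m1) - (1 - A) * e * (Y - m0)
    rng = np.random.default_rng(seed)
    n = len(A)
    idx = rng.integers(0, n, size=(n_boot, n))
    taus = num[idx].sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return float(lo), float(hi)


def fit_nuisances(X, A, Y, K: int = 5, learners: Sequence[LearnerSpec] = DEFAULT_LEARNERS,
                  seed: int = 0, inner_folds: int = 5, arm_specific: bool = False) -> NuisanceFit:
    """Cross-fit the propensity and outcome models on one completed frame and
    merge them into a single NuisanceFit."""
    ss = np.random.SeedSequence(seed)
    s_ps, s_out = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    ps = crossfit_superlearner(X, A, target="propensity", K=K, learners=learners,
                               seed=s_ps, inner_folds=inner_folds)
    out = crossfit_superlearner(X, Y, target="outcome", treatment=A, K=K, learners=learners,
                                seed=s_out, inner_folds=inner_folds, arm_specific=arm_specific)
    return ps.merged_with(out)


@dataclass
class GridResult:
    """Everything `run_grid` produces: the results grid, balance/overlap
    diagnostics, the per-imputation audit trail, and individual predicted
    risk differences per cell."""

    results: pd.DataFrame
    balance: pd.DataFrame
    audit: pd.DataFrame
    individual: dict[tuple[str, float], np.ndarray]


def run_grid(
    cohort: SimCohort,
    thresholds: Sequence[float] = THRESHOLDS_MG,
    windows: Sequence[Window] | None = None,
    learners: Sequence[LearnerSpec] = DEFAULT_LEARNERS,
    K: int = 5,
    M: int = 5,
    seed: int = 0,
    n_iter_impute: int = 10,
    arm_floor: int = DEFAULT_ARM_FLOOR,
    estimands: Sequence[str] = ("owrd",),
    trunc_levels: Sequence[float] = (0.01, 0.05),
    exclude_shock: bool = False,
    exclude_pulse: bool = False,
    inner_folds: int = 5,
) -> GridResult:
    """Run the full window x threshold grid on a cohort.

    Each window is analysed separately; within a window each patient
    contributes at most one observation; estimates are pooled across
    imputations by Rubin's rules (estimate-then-pool).  Cells with fewer than
    ``arm_floor`` patients in either arm are reported as unestimated rather
    than fabricated.  ``estimands`` may include "owrd" and "ate_trunc" (the
    latter expands over ``trunc_levels``).
    """
    windows = make_windows() if windows is None else list(windows)
    patients, doses, outcomes = cohort.patients, cohort.doses, cohort.outcomes
    if exclude_shock or exclude_pulse:
        drop = set()
        if exclude_shock:
            drop |= shock_patients(cohort.dynamics)
        if exclude_pulse:
            from .doses import pulse_dose_patients
            drop |= pulse_dose_patients(doses, [w.days for w in windows])
        keep = ~patients["patient_id"].isin(drop)
        patients = patients[keep].reset_index(drop=True)
        ids = set(patients["patient_id"])
        doses = doses[doses["patient_id"].isin(ids)].reset_index(drop=True)
        outcomes = outcomes[outcomes["patient_id"].isin(ids)].reset_index(drop=True)
        dynamics = cohort.dynamics[cohort.dynamics["patient_id"].isin(ids)]
    else:
        dynamics = cohort.dynamics
    panel = DynamicsPanel(dynamics, patients["patient_id"].to_numpy(), cohort.config.horizon_days)

    res_rows, bal_rows, audit_rows = [], [], []
    individual: dict[tuple[str, float], np.ndarray] = {}
    cell_seed = np.random.SeedSequence(seed)
    for window in windows:
        for threshold in thresholds:
            cs = int(cell_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
            frame = assemble_frame(patients, doses, outcomes, panel, window, threshold)
            label = window.label
            if frame.degenerate(max(arm_floor, 1)):
                res_rows.append(dict(
                    window=window.index, window_label=label, threshold=threshold,
                    estimand="owrd", status="degenerate",
                    reason=f"treated={frame.n_treated}, control={frame.n_control} < floor {arm_floor}",
                    n=frame.n, n_treated=frame.n_treated, n_control=frame.n_control,
                ))
                continue
            cell = _estimate_cell(frame, learners, K, M, cs, n_iter_impute,
                                  estimands, trunc_levels, inner_folds)
            individual[(label, float(threshold))] = cell["individual"]
            for est in cell["estimates"]:
                res_rows.append(dict(
                    window=window.index, window_label=label, threshold=threshold,
                    estimand=est.estimand, status="ok", reason="",
                    estimate=est.estimate, se=est.se,
                    ci_low=est.ci_low, ci_high=est.ci_high,
                    n=est.n, n_treated=est.n_treated, n_control=est.n_control,
                    ess=est.ess, M=est.M,
                ))
            bal_rows.append(dict(window=window.index, window_label=label,
                                 threshold=threshold, **cell["balance"]))
            for row in cell["audit"]:
                audit_rows.append(dict(window_label=label, threshold=threshold, **row))
    return GridResult(
        results=pd.DataFrame(res_rows),
        balance=pd.DataFrame(bal_rows),
        audit=pd.DataFrame(audit_rows),
        individual=individual,
    )


def _estimate_cell(frame: WindowFrame, learners, K, M, seed, n_iter_impute,
                   estimands, trunc_levels, inner_folds):
    """Impute -> per-copy cross-fit + estimate -> Rubin pool, for one cell."""
    A = frame.data["treated"].to_numpy()
    Y = frame.data["outcome"].to_numpy()
    Xdf = frame.X()
    M_eff = M if Xdf.isna().any().any() else 1
    stack = mice_impute(Xdf, M=M_eff, seed=seed, n_iter=n_iter_impute)

    wanted = []
    for name in estimands:
        if name == "owrd":
            wanted.append(("owrd", None))
        elif name == "ate_trunc":
            wanted.extend(("ate_trunc", t) for t in trunc_levels)
        else:
            raise ValueError(f"unknown estimand {name!r}")
    per_imp: dict[str, list] = {f"{nm}:{t}": [] for nm, t in wanted}
    diags, audit, ind_sum = [], [], None
    ss = np.random.SeedSequence(seed + 1)
    for m, cov in enumerate(stack.copies):
        fseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        fit = fit_nuisances(cov.to_numpy(), A, Y, K=K, learners=learners,
                            seed=fseed, inner_folds=inner_folds)
        for nm, t in wanted:
            est = (owrd(fit, A, Y, frame.window.label, frame.threshold) if nm == "owrd"
                   else aipw_ate_truncated(fit, A, Y, t, frame.window.label, frame.threshold))
            per_imp[f"{nm}:{t}"].append(est)
            audit.append(dict(copy=m, estimand=est.estimand, estimate=est.estimate,
                              variance=est.se**2, seed=fseed))
        auc, brier = ps_metrics(fit, A)
        bt = balance_table(cov.to_numpy(), A, fit.e, names=list(cov.columns))
        w = fit.e * (1 - fit.e)
        diags.append(dict(
            ess=ess(w), auc=auc, brier=brier,
            median_smd=float(bt["smd"].median()),
            frac_smd_lt_02=float((bt["smd"] < 0.2).mean()),
            frac_smd_lt_01=float((bt["smd"] < 0.1).mean()),
        ))
        rd = individual_rd(fit)
        ind_sum = rd if ind_sum is None else ind_sum + rd

    estimates = []
    for key, fits in per_imp.items():
        pooled = rubin_pool([f.estimate for f in fits], [f.se**2 for f in fits])
        proto = fits[0]
        estimates.append(replace(
            proto, estimate=pooled.estimate, se=pooled.se,
            ci_low=pooled.ci_low, ci_high=pooled.ci_high,
            ess=float(np.mean([f.ess for f in fits])), M=pooled.M,
        ))
    balance = {k: float(np.mean([d[k] for d in diags])) for k in diags[0]}
    balance.update(n=len(A), n_treated=int(A.sum()))
    return dict(estimates=estimates, balance=balance, audit=audit,
                individual=ind_sum / len(stack.copies))


def shock_patients(dynamics: pd.DataFrame, cutoff: float = 0.15) -> set:
    """Patients ever recorded with noradrenaline above ``cutoff`` ug/kg/min
    (the shock sensitivity exclusion)."""
    sub = dynamics[(dynamics["variable"] == "norepinephrine") & dynamics["observed"].astype(bool)]
    return set(sub.loc[sub["value"] > cutoff, "patient_id"].unique())
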