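"""Multiple imputation by chained equations on a window frame's covariate
block, and Rubin's rules for pooling per-imputation estimates.

The chained-equations sweep follows the conventional proper-imputation
recipe: continuous columns are imputed from a Bayesian linear model (a
coefficient draw from its approximate posterior plus a residual noise draw),
binary columns from a logistic model with a Bernoulli draw.  Imputation is
run per window frame — each window is analysed separately — and everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_M = 5
DEFAULT_N_ITER = 10


@dataclass
class ImputedStack:
    """M completed copies of a covariate block (observed cells identical)."""

    copies: list[pd.DataFrame]
    seeds: list[int]

    @property
    def M(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled point estimate with within/between variance split."""

    estimate: float
    within: float
    between: float
    total: float
    ci_low: float
    ci_high: float
    M: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def mice_impute(
    covariates: pd.DataFrame,
    M: int = DEFAULT_M,
    seed: int = 0,
    n_iter: int = DEFAULT_N_ITER,
) -> ImputedStack:
    """Chained-equations multiple imputation of a numeric covariate block.

    Columns with any observed values are imputed; a column with zero observed
    values is an error (it carries no information to impute from).  Requires
    at least one fully observed column.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    X = covariates.astype(float)
    miss = X.isna()
    all_missing = [c for c in X.columns if miss[c].all()]
    if all_missing:
        raise ValueError(f"column(s) with zero observed values: {all_missing}")
    if not (~miss).all(axis=0).any():
        raise ValueError("chained equations need at least one fully observed column")
    incomplete = [c for c in X.columns if miss[c].any()]
    if not incomplete:
        return ImputedStack([X.copy() for _ in range(M)], seeds=[seed] * M)

    binary = {c: _is_binary(X[c].to_numpy()) for c in incomplete}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(M)]
    copies = []
    for m in range(M):
        rng = np.random.default_rng(child_seeds[m])
        filled = X.copy()
        for c in incomplete:  # initial fill: observed mean / mode
            obs = X[c].dropna()
            init = float(obs.mean() >= 0.5) if binary[c] else float(obs.mean())
            filled.loc[miss[c], c] = init
        for _ in range(n_iter):
            for c in incomplete:
                others = [k for k in X.columns if k != c]
                A = filled[others].to_numpy()
                A = np.column_stack([np.ones(len(A)), A])
                obs_mask = (~miss[c]).to_numpy()
                y_obs = X.loc[obs_mask, c].to_numpy()
                if binary[c]:
                    p = _logistic_draw(A[obs_mask], y_obs, A[~obs_mask], rng)
                    filled.loc[miss[c], c] = (rng.random(p.size) < p).astype(float)
                else:
                    draw = _bayes_linear_draw(A[obs_mask], y_obs, A[~obs_mask], rng)
                    filled.loc[miss[c], c] = draw
        copies.append(filled)
    return ImputedStack(copies, seeds=child_seeds)


def _bayes_linear_draw(Ao: np.ndarray, y: np.ndarray, Am: np.ndarray, rng) -> np.ndarray:
    """Predict missing continuous cells with a posterior coefficient draw plus
    residual noise (ridge-stabilised normal-equations solve)."""
    n, p = Ao.shape
    gram = Ao.T @ Ao + 1e-6 * np.eye(p)
    beta = np.linalg.solve(gram, Ao.T @ y)
    resid = y - Ao @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = sigma2 * dof / max(stats.chi2.rvs(dof, random_state=rng), 1e-12)
    cov = sigma2_draw * np.linalg.inv(gram)
    beta_draw = rng.multivariate_normal(beta, cov, method="cholesky")
    return Am @ beta_draw + rng.normal(0.0, np.sqrt(sigma2_draw), size=len(Am))


def _logistic_draw(Ao: np.ndarray, y: np.ndarray, Am: np.ndarray, rng) -> np.ndarray:
    """Fitted logistic probabilities for missing binary cells (degenerate
    observed columns fall back to the observed rate)."""
    if np.unique(y).size < 2:
        return np.full(len(Am), float(np.mean(y)))
    from sklearn.linear_model import LogisticRegression

    model = LogisticRegression(C=1e4, max_iter=200)
    model.fit(Ao[:, 1:], y)
    return model.predict_proba(Am[:, 1:])[:, 1]


Z_975 = float(stats.norm.ppf(0.975))


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool M per-imputation estimates by Rubin's rules.

    point = mean(estimates); W = mean(variances); B = sample variance of the
    estimates (0 when M = 1); T = W + (1 + 1/M) B; normal-reference 95% CI.
    """
    est = np.asarray(list(estimates), dtype=float)
    var = np.asarray(list(variances), dtype=float)
    if est.size == 0:
        raise ValueError("cannot pool zero imputations")
    if est.size != var.size:
        raise ValueError("estimates and variances must have equal length")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    M = est.size
    point = float(est.mean())
    W = float(var.mean())
    B = float(np.var(est, ddof=1)) if M > 1 else 0.0
    T = W + (1.0 + 1.0 / M) * B
    half = Z_975 * np.sqrt(T)
    return PooledEstimate(
        estimate=point,
        within=W,
        between=B,
        total=T,
        ci_low=point - half,
        ci_high=point + half,
        M=M,
    )
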