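"""Cross-fitted super-learner nuisance models.

Both nuisance functions — the within-window propensity score e(x) and the
outcome-risk model m(a, x) — are fit with a convex ensemble of candidate
learners (logistic GLM, penalized GLM, random forest, shallow gradient
boosting).  Ensemble weights are chosen on the probability simplex by
minimising cross-validated negative log-likelihood (exponentiated-gradient
iterations, tolerance 1e-8).  Out-of-fold predictions come from a K-fold
outer split, so every row is predicted by models that never saw its fold.

The outcome model is fit on the pooled frame with treatment as a feature and
m1/m0 obtained by toggling that feature (arm-specific fits are unstable in
late windows with few treated patients); an arm-specific option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import brier_score_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

EPS = 1e-6  #: probability clip before any log

LEARNER_NAMES = ("glm", "penalized_glm", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class LearnerSpec:
    """One candidate learner by name, with hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; known: {LEARNER_NAMES}")


DEFAULT_LEARNERS: tuple[LearnerSpec, ...] = tuple(LearnerSpec(n) for n in LEARNER_NAMES)
GLM_ONLY: tuple[LearnerSpec, ...] = (LearnerSpec("glm"),)


def make_estimator(spec: LearnerSpec, seed: int):
    if spec.name == "glm":
        # scaling only conditions the optimiser; penalty-free optimum unchanged
        kw = dict(C=np.inf, max_iter=2000)
        kw.update(spec.params)
        return make_pipeline(StandardScaler(), LogisticRegression(**kw))
    if spec.name == "penalized_glm":
        kw = dict(Cs=6, penalty="elasticnet", solver="saga", l1_ratios=[0.5],
                  cv=3, max_iter=300, tol=1e-3, random_state=seed)
        kw.update(spec.params)
        return make_pipeline(StandardScaler(), LogisticRegressionCV(**kw))
    if spec.name == "random_forest":
        kw = dict(n_estimators=500, min_samples_leaf=10, random_state=seed, n_jobs=1)
        kw.update(spec.params)
        return RandomForestClassifier(**kw)
    if spec.name == "gradient_boosting":
        kw = dict(max_depth=2, max_iter=200, learning_rate=0.05,
                  early_stopping=False, random_state=seed)
        kw.update(spec.params)
        return HistGradientBoostingClassifier(**kw)
    raise ValueError(spec.name)


@dataclass
class NuisanceFit:
    """Out-of-fold nuisance predictions for one window frame (one copy)."""

    fold_id: np.ndarray
    e: np.ndarray | None = None
    m1: np.ndarray | None = None
    m0: np.ndarray | None = None
    ensemble_weights: list[dict[str, float]] = field(default_factory=list)

    def merged_with(self, other: "NuisanceFit") -> "NuisanceFit":
        """Combine a propensity fit and an outcome fit into one object."""
        return NuisanceFit(
            fold_id=self.fold_id,
            e=self.e if self.e is not None else other.e,
            m1=self.m1 if self.m1 is not None else other.m1,
            m0=self.m0 if self.m0 is not None else other.m0,
            ensemble_weights=self.ensemble_weights + other.ensemble_weights,
        )


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def _fit_predict(est, X_tr, y_tr, X_list):
    """Fit and predict P(y=1) on each matrix in X_list; a single-class
    training fold degenerates to its constant rate."""
    if np.unique(y_tr).size < 2:
        rate = float(np.mean(y_tr))
        return [np.full(len(X), rate) for X in X_list]
    est.fit(X_tr, y_tr)
    return [est.predict_proba(X)[:, 1] for X in X_list]


def simplex_weights(pred: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 10_000, step: float = 1.0) -> np.ndarray:
    """Minimise CV negative log-likelihood of a convex combination of learner
    probability columns over the simplex by exponentiated gradient."""
    pred = _clip(np.asarray(pred, dtype=float))
    L = pred.shape[1]
    w = np.full(L, 1.0 / L)
    n = len(y)
    for _ in range(max_iter):
        p = _clip(pred @ w)
        grad = -(pred * (y / p - (1 - y) / (1 - p))[:, None]).mean(axis=0)
        w_new = w * np.exp(-step * (grad - grad.min()))
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    # byte-identical learners: give the combined mass to the first of them
    for i in range(L):
        for j in range(i + 1, L):
            if np.max(np.abs(pred[:, i] - pred[:, j])) < 1e-12 and w[j] > 0:
                w[i] += w[j]
                w[j] = 0.0
    return w / w.sum()


def crossfit_superlearner(
    X,
    y,
    target: str,
    treatment: np.ndarray | None = None,
    K: int = 5,
    learners: Sequence[LearnerSpec] = DEFAULT_LEARNERS,
    seed: int = 0,
    inner_folds: int = 5,
    folds: np.ndarray | None = None,
    arm_specific: bool = False,
) -> NuisanceFit:
    """Out-of-fold super-learner predictions.

    target="propensity": y is the treatment indicator; returns e(x).
    target="outcome": y is the outcome, ``treatment`` must be given; returns
    m1(x) and m0(x) by toggling the treatment feature (or by arm-specific
    fits when ``arm_specific``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if target not in ("propensity", "outcome"):
        raise ValueError("target must be 'propensity' or 'outcome'")
    if target == "outcome":
        if treatment is None:
            raise ValueError("outcome target needs the treatment indicator")
        treatment = np.asarray(treatment).astype(int)
        strat = treatment
    else:
        strat = y
    if not np.isfinite(X).all():
        raise ValueError("covariate matrix contains NaN/inf; impute first")
    counts = np.bincount(strat, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"an arm is (near) empty: treated={counts[1]}, control={counts[0]}; "
            "cannot form stratified folds"
        )
    if n < 2 * K:
        raise ValueError(f"n={n} too small for K={K} cross-fitting")
    ss = np.random.SeedSequence(seed)
    fold_seed, *learner_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(learners) + 1)]
    if folds is None:
        K_eff = min(K, counts.min())  # stratified refold attempt for tiny arms
        skf = StratifiedKFold(n_splits=K_eff, shuffle=True, random_state=fold_seed)
        folds = np.empty(n, dtype=int)
        for k, (_, te) in enumerate(skf.split(X, strat)):
            folds[te] = k
    else:
        folds = np.asarray(folds, dtype=int)

    if target == "outcome" and not arm_specific:
        feats = np.column_stack([X, treatment])
        feats1 = np.column_stack([X, np.ones(n)])
        feats0 = np.column_stack([X, np.zeros(n)])
    e = np.full(n, np.nan)
    m1 = np.full(n, np.nan)
    m0 = np.full(n, np.nan)
    all_weights = []
    for k in np.unique(folds):
        tr = folds != k
        te = folds == k
        if target == "outcome" and np.unique(treatment[tr]).size < 2:
            raise ValueError(f"training fold {k} lost an arm; reduce K or pool windows")
        w = _ensemble_weights_for_fold(
            X, y, treatment, target, tr, learners, learner_seeds, inner_folds, arm_specific
        )
        all_weights.append({spec.name: float(wi) for spec, wi in zip(learners, w)})
        for spec, wi, lseed in zip(learners, w, learner_seeds):
            if wi <= 0:
                continue
            est = make_estimator(spec, lseed)
            if target == "propensity":
                (pe,) = _fit_predict(est, X[tr], y[tr], [X[te]])
                e[te] = np.where(np.isnan(e[te]), 0.0, e[te]) + wi * pe
            elif arm_specific:
                tr1 = tr & (treatment == 1)
                tr0 = tr & (treatment == 0)
                (p1,) = _fit_predict(est, X[tr1], y[tr1], [X[te]])
                est0 = make_estimator(spec, lseed)
                (p0,) = _fit_predict(est0, X[tr0], y[tr0], [X[te]])
                m1[te] = np.where(np.isnan(m1[te]), 0.0, m1[te]) + wi * p1
                m0[te] = np.where(np.isnan(m0[te]), 0.0, m0[te]) + wi * p0
            else:
                p1, p0 = _fit_predict(est, feats[tr], y[tr], [feats1[te], feats0[te]])
                m1[te] = np.where(np.isnan(m1[te]), 0.0, m1[te]) + wi * p1
                m0[te] = np.where(np.isnan(m0[te]), 0.0, m0[te]) + wi * p0

    if target == "propensity":
        return NuisanceFit(fold_id=folds, e=_clip(e), ensemble_weights=all_weights)
    return NuisanceFit(fold_id=folds, m1=_clip(m1), m0=_clip(m0), ensemble_weights=all_weights)


def _ensemble_weights_for_fold(X, y, treatment, target, tr, learners,
                               learner_seeds, inner_folds, arm_specific):
    """Inner-CV loss per learner within one training fold -> simplex weights."""
    if len(learners) == 1:
        return np.array([1.0])
    idx = np.flatnonzero(tr)
    y_tr = y[idx]
    strat = y_tr if np.unique(y_tr).size > 1 else np.zeros(len(idx), dtype=int)
    V = min(inner_folds, max(2, np.bincount(strat, minlength=2).min()))
    if np.unique(strat).size < 2:
        return np.full(len(learners), 1.0 / len(learners))
    skf = StratifiedKFold(n_splits=V, shuffle=True, random_state=learner_seeds[0])
    if target == "outcome":
        feats = np.column_stack([X, treatment])[idx]  # pooled frame for weight CV
    else:
        feats = X[idx]
    cv_pred = np.full((len(idx), len(learners)), np.nan)
    for itr, ite in skf.split(feats, strat):
        for j, (spec, lseed) in enumerate(zip(learners, learner_seeds)):
            est = make_estimator(spec, lseed)
            (p,) = _fit_predict(est, feats[itr], y_tr[itr], [feats[ite]])
            cv_pred[ite, j] = p
    return simplex_weights(cv_pred, y_tr)


def ps_metrics(fit: NuisanceFit, treatment) -> tuple[float, float]:
    """Propensity discrimination (AUC by rank statistic over out-of-fold
    e-hat) and calibration (Brier score)."""
    A = np.asarray(treatment).astype(int)
    if np.unique(A).size < 2:
        raise ValueError("both exposure classes must be present for PS metrics")
    if fit.e is None:
        raise ValueError("fit has no propensity predictions")
    return float(roc_auc_score(A, fit.e)), float(brier_score_loss(A, fit.e))


def fit_mle_propensity(X, A) -> np.ndarray:
    """Maximum-likelihood logistic propensity (no cross-fitting, no penalty),
    converged tightly so the exact-balance property of overlap weights holds
    to numerical tolerance.

    Columns are standardised internally (the fit is affine-equivariant, so
    the score equations — and hence exact balance — carry over to the raw
    covariates); zero-variance columns are dropped.  Newton with a BFGS
    warm-start fallback for nearly separated frames.
    """
    import warnings

    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    A = np.asarray(A).astype(int)
    keep = X.std(axis=0) > 0
    Xs = X[:, keep]
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)
    Xc = sm.add_constant(Xs, has_constant="add")
    model = sm.Logit(A, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", tol=1e-12, maxiter=500, disp=0)
        except np.linalg.LinAlgError:
            start = model.fit(method="bfgs", gtol=1e-10, maxiter=2000, disp=0)
            res = model.fit(method="newton", tol=1e-12, maxiter=500, disp=0,
                            start_params=start.params)
    return np.asarray(res.predict(Xc), dtype=float)
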