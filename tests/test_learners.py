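"""Cross-fitted super learner: weights, honesty, metrics."""

import numpy as np
import pytest
from scipy.special import expit

from cortiwin.learners import (
    GLM_ONLY,
    LearnerSpec,
    crossfit_superlearner,
    fit_mle_propensity,
    ps_metrics,
    simplex_weights,
)


def _logistic_data(n, seed, beta=(1.0, -1.0, 0.5)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    p = expit(X @ np.asarray(beta))
    return X, (rng.random(n) < p).astype(int), p


class TestSimplexWeights:
    def test_single_learner_gets_weight_one(self):
        X, y, _ = _logistic_data(300, 0)
        fit = crossfit_superlearner(X, y, target="propensity", learners=GLM_ONLY, seed=1)
        for w in fit.ensemble_weights:
            assert w == {"glm": 1.0}

    def test_identical_learners_invariant_combination(self):
        """Two byte-identical prediction columns: any split of weight between
        them yields the same combined prediction, and the solver collapses
        the mass onto the first."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=200)
        y = (rng.random(200) < p).astype(int)
        pred = np.column_stack([p, p])
        w = simplex_weights(pred, y)
        assert w[0] == pytest.approx(1.0)
        assert np.allclose(pred @ w, p)

    def test_weights_are_simplex(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 300)
        pred = np.column_stack([
            rng.uniform(0.1, 0.9, 300),
            np.where(y == 1, 0.8, 0.2),  # informative column
            rng.uniform(0.4, 0.6, 300),
        ])
        w = simplex_weights(pred, y)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert w[1] > 0.5  # mass concentrates on the informative learner


class TestCrossfit:
    def test_ensemble_not_much_worse_than_worst_learner(self):
        """On a logistic DGP the CV-weighted ensemble's propensity AUC is at
        least the worst single learner's minus 0.01."""
        X, A, _ = _logistic_data(4000, 10)
        learners = (LearnerSpec("glm"),
                    LearnerSpec("gradient_boosting", {"max_iter": 60}))
        aucs = []
        for lib in (learners, (learners[0],), (learners[1],)):
            fit = crossfit_superlearner(X, A, target="propensity", learners=lib,
                                        seed=5, inner_folds=3)
            auc, _ = ps_metrics(fit, A)
            aucs.append(auc)
        assert aucs[0] >= min(aucs[1:]) - 0.01

    def test_out_of_fold_honesty(self):
        """Honest cross-fitting: a row's prediction comes from models never
        trained on its fold, so perturbing one row leaves the predictions of
        the *other rows in its own fold* untouched (models predicting other
        folds do see the perturbed row and may change)."""
        X, A, _ = _logistic_data(200, 6)
        folds = np.arange(200) % 4
        fit1 = crossfit_superlearner(X, A, target="propensity", learners=GLM_ONLY,
                                     K=4, seed=9, folds=folds)
        X2 = X.copy()
        X2[0] += 5.0  # row 0 lives in fold 0
        fit2 = crossfit_superlearner(X2, A, target="propensity", learners=GLM_ONLY,
                                     K=4, seed=9, folds=folds)
        changed = fit1.e != fit2.e
        assert not changed[(folds == 0) & (np.arange(200) != 0)].any()
        # sanity: the perturbation did move other folds' models
        assert changed.any()

    def test_seeded_determinism(self):
        X, A, _ = _logistic_data(400, 8)
        f1 = crossfit_superlearner(X, A, target="propensity", learners=GLM_ONLY, seed=3)
        f2 = crossfit_superlearner(X, A, target="propensity", learners=GLM_ONLY, seed=3)
        assert np.array_equal(f1.e, f2.e)
        assert np.array_equal(f1.fold_id, f2.fold_id)

    def test_outcome_target_toggles_treatment(self):
        rng = np.random.default_rng(11)
        X, A, _ = _logistic_data(600, 12)
        Y = (rng.random(600) < expit(X[:, 0] + 1.2 * A - 0.5)).astype(int)
        fit = crossfit_superlearner(X, Y, target="outcome", treatment=A,
                                    learners=GLM_ONLY, seed=2)
        assert fit.m1 is not None and fit.m0 is not None
        assert (fit.m1 > fit.m0).mean() > 0.9  # positive treatment coefficient
        assert ((fit.m1 > 0) & (fit.m1 < 1)).all()

    def test_predictions_clipped_away_from_0_1(self):
        X, A, _ = _logistic_data(300, 13, beta=(8.0,))  # near-separable
        fit = crossfit_superlearner(X, A, target="propensity", learners=GLM_ONLY, seed=1)
        assert (fit.e >= 1e-6).all() and (fit.e <= 1 - 1e-6).all()

    def test_empty_arm_refused(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="arm"):
            crossfit_superlearner(X, np.ones(50, dtype=int), target="propensity",
                                  learners=GLM_ONLY, seed=0)


class TestPsMetrics:
    def test_perfect_separation_auc_one(self):
        from cortiwin.learners import NuisanceFit
        A = np.array([0, 0, 1, 1])
        fit = NuisanceFit(fold_id=np.zeros(4), e=np.array([0.1, 0.2, 0.8, 0.9]))
        auc, brier = ps_metrics(fit, A)
        assert auc == 1.0

    def test_constant_half_brier_quarter(self):
        from cortiwin.learners import NuisanceFit
        A = np.array([0, 1, 0, 1])
        fit = NuisanceFit(fold_id=np.zeros(4), e=np.full(4, 0.5))
        auc, brier = ps_metrics(fit, A)
        assert brier == pytest.approx(0.25)

    def test_uninformative_auc_half(self):
        rng = np.random.default_rng(1)
        A = rng.integers(0, 2, 4000)
        from cortiwin.learners import NuisanceFit
        fit = NuisanceFit(fold_id=np.zeros(4000), e=rng.uniform(0.2, 0.8, 4000))
        auc, _ = ps_metrics(fit, A)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_raises(self):
        from cortiwin.learners import NuisanceFit
        fit = NuisanceFit(fold_id=np.zeros(3), e=np.array([0.2, 0.5, 0.7]))
        with pytest.raises(ValueError):
            ps_metrics(fit, np.ones(3, dtype=int))


def test_mle_propensity_score_equations():
    """ML logistic fit satisfies the score equations sum((A - e) x) = 0 to
    high precision — the basis of the exact-balance property."""
    X, A, _ = _logistic_data(500, 21)
    e = fit_mle_propensity(X, A)
    resid = A - e
    assert abs(resid.sum()) < 1e-8
    assert np.abs(X.T @ resid).max() < 1e-6
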