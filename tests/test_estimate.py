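"""OWRD / AIPW estimators: hand-computable examples, exact-balance oracle,
degenerate-frame refusal, and the grid runner."""

import numpy as np
import pandas as pd
import pytest

from cortiwin.diagnostics import balance_table, balancing_weights
from cortiwin.estimate import (
    NoOverlapError,
    aipw_ate_truncated,
    individual_rd,
    owrd,
    run_grid,
)
from cortiwin.learners import GLM_ONLY, NuisanceFit, fit_mle_propensity
from cortiwin.windows import assemble_frame, make_windows


def _fit(e, m1, m0):
    n = len(e)
    return NuisanceFit(fold_id=np.zeros(n, dtype=int),
                       e=np.asarray(e, float), m1=np.asarray(m1, float),
                       m0=np.asarray(m0, float))


class TestOwrd:
    def test_four_row_hand_example(self):
        """e=0.5, m1=0.6, m0=0.4 for all four rows with (A,Y) covering the
        2x2: per-row numerators +0.25, -0.25, -0.25, +0.25 -> tau = 0."""
        fit = _fit([0.5] * 4, [0.6] * 4, [0.4] * 4)
        A = np.array([1, 1, 0, 0])
        Y = np.array([1, 0, 1, 0])
        est = owrd(fit, A, Y)
        assert est.estimate == pytest.approx(0.0, abs=1e-12)

    def test_zero_residuals_reduce_to_weighted_outcome_contrast(self):
        """When Y equals the arm-specific prediction exactly, the
        augmentation vanishes and tau = sum w (m1-m0) / sum w."""
        rng = np.random.default_rng(0)
        n = 50
        e = rng.uniform(0.2, 0.8, n)
        m1 = rng.uniform(0.5, 0.9, n)
        m0 = rng.uniform(0.1, 0.5, n)
        A = (rng.random(n) < 0.5).astype(int)
        # binary outcomes cannot equal m exactly; use the algebraic contract
        # with degenerate predictions instead
        m1b = A.astype(float)
        m0b = np.zeros(n)
        Y = np.where(A == 1, 1, 0)
        fit = _fit(e, m1b, m0b)
        w = e * (1 - e)
        expected = float(np.sum(w * (m1b - m0b)) / w.sum())
        assert owrd(fit, A, Y).estimate == pytest.approx(expected, abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        n = 200
        fit = _fit(rng.uniform(0.05, 0.95, n), rng.uniform(0, 1, n), rng.uniform(0, 1, n))
        A = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.3).astype(int)
        est = owrd(fit, A, Y)
        assert -1.0 <= est.estimate <= 1.0
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_degenerate_frame_refused(self):
        fit = _fit([0.5] * 4, [0.5] * 4, [0.5] * 4)
        with pytest.raises(NoOverlapError):
            owrd(fit, np.ones(4, dtype=int), np.zeros(4, dtype=int))


class TestAipwTruncated:
    def test_equal_to_untruncated_when_inside_band(self):
        rng = np.random.default_rng(1)
        n = 100
        e = rng.uniform(0.2, 0.8, n)
        fit = _fit(e, rng.uniform(0.4, 0.6, n), rng.uniform(0.2, 0.4, n))
        A = (rng.random(n) < 0.5).astype(int)
        Y = (rng.random(n) < 0.3).astype(int)
        est_a = aipw_ate_truncated(fit, A, Y, trunc=0.01)
        est_b = aipw_ate_truncated(fit, A, Y, trunc=0.05)
        assert est_a.estimate == pytest.approx(est_b.estimate, abs=1e-12)

    def test_truncation_clips_extreme_propensities(self):
        e = np.array([0.005, 0.5, 0.5, 0.995])
        fit = _fit(e, [0.5] * 4, [0.5] * 4)
        A = np.array([1, 1, 0, 0])
        Y = np.array([1, 0, 1, 0])
        t1 = aipw_ate_truncated(fit, A, Y, trunc=0.01).estimate
        t5 = aipw_ate_truncated(fit, A, Y, trunc=0.05).estimate
        assert t1 != t5  # clipping changed the extreme rows' weights


class TestIndividualRd:
    def test_identical_predictions_all_zero(self):
        fit = _fit([0.5] * 5, [0.3] * 5, [0.3] * 5)
        assert np.allclose(individual_rd(fit), 0.0)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        fit = _fit(rng.uniform(0.1, 0.9, 50), rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))
        rd = individual_rd(fit)
        assert (rd >= -1).all() and (rd <= 1).all()


class TestExactBalance:
    def test_logistic_overlap_weights_balance_covariates(self, complete_cohort, complete_panel):
        """Maximum-likelihood logistic propensity + overlap weights equalise
        the weighted mean of every propensity covariate between arms —
        an analytic property, checked to 1e-6."""
        c = complete_cohort
        frame = assemble_frame(c.patients, c.doses, c.outcomes, complete_panel,
                               make_windows()[1], 30.0)
        X = frame.X().to_numpy()
        A = frame.data["treated"].to_numpy()
        e = fit_mle_propensity(X, A)
        w = balancing_weights(e, A)
        for j in range(X.shape[1]):
            if X[:, j].std() == 0:
                continue
            m1 = np.average(X[A == 1, j], weights=w[A == 1])
            m0 = np.average(X[A == 0, j], weights=w[A == 0])
            assert abs(m1 - m0) < 1e-6, f"covariate {frame.covariates[j]} unbalanced"


class TestRunGrid:
    @pytest.fixture(scope="class")
    def grid(self, complete_cohort):
        return run_grid(complete_cohort, thresholds=(30.0, 390.0),
                        windows=make_windows()[:4], learners=GLM_ONLY,
                        M=2, seed=3, arm_floor=5)

    def test_all_cells_attempted(self, grid):
        assert len(grid.results) == 4 * 2  # every cell reported, ok or degenerate
        assert set(grid.results["status"]) <= {"ok", "degenerate"}

    def test_ok_cells_have_cis_and_ess(self, grid):
        ok = grid.results[grid.results["status"] == "ok"]
        assert len(ok) > 0
        assert (ok["ci_low"] <= ok["estimate"]).all()
        assert (ok["estimate"] <= ok["ci_high"]).all()
        assert (ok["ess"] <= ok["n"]).all()
        assert (ok["ess"] > 0).all()

    def test_audit_reproduces_pooled_estimates(self, grid):
        """Audit-trail property: each pooled cell estimate is the mean of its
        saved per-imputation estimates."""
        from cortiwin.impute import rubin_pool
        ok = grid.results[grid.results["status"] == "ok"]
        for _, row in ok.iterrows():
            sub = grid.audit[
                (grid.audit["window_label"] == row["window_label"])
                & (grid.audit["threshold"] == row["threshold"])
                & (grid.audit["estimand"] == row["estimand"])
            ]
            pooled = rubin_pool(sub["estimate"], sub["variance"])
            assert row["estimate"] == pytest.approx(pooled.estimate, abs=1e-12)

    def test_complete_data_collapses_to_single_imputation(self, complete_cohort):
        """With no missing covariates the pooled pipeline equals the
        single-frame estimate exactly (M copies would be identical)."""
        g1 = run_grid(complete_cohort, thresholds=(30.0,), windows=make_windows()[:1],
                      learners=GLM_ONLY, M=1, seed=9)
        g5 = run_grid(complete_cohort, thresholds=(30.0,), windows=make_windows()[:1],
                      learners=GLM_ONLY, M=5, seed=9)
        r1 = g1.results.iloc[0]
        r5 = g5.results.iloc[0]
        assert r5["M"] == 1
        assert r1["estimate"] == pytest.approx(r5["estimate"], abs=1e-12)

    def test_sensitivity_exclusions_reduce_n(self, complete_cohort):
        g_all = run_grid(complete_cohort, thresholds=(30.0,), windows=make_windows()[:1],
                         learners=GLM_ONLY, M=1, seed=9)
        g_sens = run_grid(complete_cohort, thresholds=(30.0,), windows=make_windows()[:1],
                          learners=GLM_ONLY, M=1, seed=9,
                          exclude_shock=True, exclude_pulse=True)
        assert g_sens.results.iloc[0]["n"] < g_all.results.iloc[0]["n"]
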