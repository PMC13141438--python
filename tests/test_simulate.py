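"""Synthetic-cohort generator and its Monte-Carlo ground-truth oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import cortiwin as cw
from cortiwin.simulate import (
    Missingness,
    OutcomeModel,
    SimConfig,
    TreatmentPolicy,
    naive_contrast,
    scenario_config,
    simulate_cohort,
    simulate_quadratic_frame,
    true_ato,
)
from cortiwin.windows import DynamicsPanel, assemble_frame, make_windows


class TestDeterminismAndShapes:
    def test_same_seed_identical_cohorts(self):
        cfg = SimConfig(n_patients=100, seed=1)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for name in ("patients", "doses", "dynamics", "outcomes"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimConfig(n_patients=100, seed=1))
        b = simulate_cohort(SimConfig(n_patients=100, seed=2))
        assert not a.outcomes.equals(b.outcomes)

    def test_referential_integrity_and_conservation(self, small_cohort):
        c = small_cohort
        ids = set(c.patients["patient_id"])
        for table in (c.doses, c.dynamics, c.outcomes):
            assert set(table["patient_id"]) <= ids
        # every patient has exactly one outcome row
        assert c.outcomes["patient_id"].is_unique and len(c.outcomes) == len(ids)
        # no dynamics after the death day; bounded row count
        merged = c.dynamics.merge(c.outcomes, on="patient_id")
        dead = merged[merged["death_day"].notna()]
        assert (dead["hour"] // 24 <= dead["death_day"]).all()
        n_vars = c.dynamics["variable"].nunique()
        per_patient = c.dynamics.groupby("patient_id").size()
        assert (per_patient <= c.config.horizon_days * n_vars).all()
        # missing flag false <=> value absent
        assert c.dynamics.loc[~c.dynamics["observed"], "value"].isna().all()
        assert c.dynamics.loc[c.dynamics["observed"], "value"].notna().all()
        # ICU deaths are flagged as hospital deaths
        icu_dead = c.outcomes["death_day"].notna()
        assert c.outcomes.loc[icu_dead, "hospital_mortality"].all()


class TestDegenerateConfigs:
    def test_never_treat_policy_empty_doses(self):
        cfg = scenario_config("no-treatment", 200, seed=3)
        cohort = simulate_cohort(cfg)
        assert len(cohort.doses[cohort.doses["day_bin"] >= 0]) == 0

    def test_zero_hazard_everyone_survives(self):
        cfg = SimConfig(
            n_patients=300, seed=4,
            outcome=OutcomeModel(intercept=-np.inf, severity=0.0,
                                 ward_intercept=-np.inf, ward_severity=0.0),
        )
        cohort = simulate_cohort(cfg)
        assert cohort.outcomes["death_day"].isna().all()
        assert not cohort.outcomes["hospital_mortality"].any()

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)
        with pytest.raises(ValueError):
            SimConfig(n_patients=10, horizon_days=2)
        with pytest.raises(ValueError):
            SimConfig(n_patients=10,
                      policy=TreatmentPolicy(intercept=float("nan")))
        with pytest.raises(ValueError):
            SimConfig(n_patients=10, outcome=OutcomeModel(intercept=np.inf))
        with pytest.raises(ValueError):
            scenario_config("nope", 10)


class TestConfoundingKnob:
    def test_severity_link_strengthens_observed_imbalance(self):
        """Raising the severity->treatment coefficient increases the
        treated-minus-control gap in window severity summaries (and degrades
        covariate balance) monotonically over three settings."""
        gaps, fracs = [], []
        from cortiwin.diagnostics import balance_table
        for coef in (0.0, 1.3, 2.6):
            cfg = scenario_config("null-complete", 4000, seed=11)
            cfg = dataclasses.replace(
                cfg, policy=dataclasses.replace(cfg.policy, severity=coef))
            c = simulate_cohort(cfg)
            panel = DynamicsPanel(c.dynamics, c.patients["patient_id"].to_numpy(), 15)
            fr = assemble_frame(c.patients, c.doses, c.outcomes, panel,
                                make_windows()[0], 30.0)
            g = fr.data.groupby("treated")["norepinephrine_mean"].mean()
            gaps.append(g[1] - g[0])
            bt = balance_table(fr.X().to_numpy(), fr.data["treated"].to_numpy(),
                               np.full(fr.n, 0.5), names=fr.covariates)
            fracs.append((bt["smd"] < 0.2).mean())
        assert gaps[0] < gaps[1] < gaps[2]
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_naive_contrast_biased_but_truth_null(self):
        """Confounded null world: the unadjusted treated-minus-control
        mortality difference is clearly positive while the causal truth is
        zero."""
        cfg = scenario_config("null-complete", 6000, seed=17)
        c = simulate_cohort(cfg)
        panel = DynamicsPanel(c.dynamics, c.patients["patient_id"].to_numpy(), 15)
        fr = assemble_frame(c.patients, c.doses, c.outcomes, panel,
                            make_windows()[0], 30.0)
        assert naive_contrast(fr.data) > 0.02
        rd, se = true_ato(cfg, (0, 2), 30.0, n_mc=4000, seed=5, inner_draws=32)
        assert abs(rd) <= 3 * max(se, 1e-6)


class TestOracle:
    def test_null_effect_is_zero(self):
        cfg = scenario_config("null-complete", 100, seed=2)
        for window in ((0, 2), (5, 7)):
            rd, se = true_ato(cfg, window, 30.0, n_mc=2000, seed=3, inner_draws=32)
            assert abs(rd) <= 3 * max(se, 1e-9)

    def test_constant_terminal_effect_recovered(self):
        """With no baseline or ward mortality and a surcharge schedule that is
        0.10 inside days 0-2 and zero afterwards, every eligible subject has
        r1 - r0 = 0.10 exactly, so the overlap-weighted truth is 0.10."""
        sched = tuple(0.10 if d <= 2 else 0.0 for d in range(15))
        cfg = SimConfig(
            n_patients=100, seed=6,
            outcome=OutcomeModel(intercept=-np.inf, severity=0.0,
                                 ward_intercept=-np.inf, ward_severity=0.0,
                                 effect_type="terminal", effect_by_day=sched),
            missingness=Missingness(rates={}, severity_relief=0.0),
        )
        rd, se = true_ato(cfg, (0, 2), 30.0, n_mc=4000, seed=9, inner_draws=64)
        assert rd == pytest.approx(0.10, abs=3 * max(se, 1e-4))

    def test_self_consistency_across_mc_sizes(self):
        cfg = scenario_config("homogeneous", 100, seed=8)
        rd1, se1 = true_ato(cfg, (1, 3), 30.0, n_mc=2000, seed=21, inner_draws=32)
        rd2, se2 = true_ato(cfg, (1, 3), 30.0, n_mc=8000, seed=22, inner_draws=32)
        assert abs(rd1 - rd2) <= 3 * np.sqrt(se1**2 + se2**2) + 0.01

    def test_window_and_nmc_validation(self):
        cfg = scenario_config("null", 100, seed=1)
        with pytest.raises(ValueError):
            true_ato(cfg, (13, 15), 30.0, n_mc=2000, seed=0)
        with pytest.raises(ValueError):
            true_ato(cfg, (0, 2), 30.0, n_mc=500, seed=0)


def test_quadratic_frame_confounded_null():
    df, A, Y = simulate_quadratic_frame(20000, seed=1)
    # treated have systematically larger x3^2 (the hidden confounder)...
    assert df.loc[A == 1, "x3sq"].mean() > df.loc[A == 0, "x3sq"].mean() + 0.2
    # ...and higher raw mortality despite the null effect
    assert Y[A == 1].mean() > Y[A == 0].mean() + 0.02
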