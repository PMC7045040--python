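"""Constrained ML estimation: OLS equivalence, constraints, fit indices,
nested tests, multilevel path."""

import numpy as np
import pandas as pd
import pytest

import memlag as ml
from memlag.estimation import (
    ConstraintSpec,
    ModelSpec,
    RankDeficientDesignError,
    fit_indices,
    fit_multilevel,
    fit_pooled,
    model_m0,
    model_m1,
    model_m2,
    model_m3,
    nested_chi2_test,
)
from memlag.panel import WEEKDAYS
from memlag.transform import LagSpec, build_lag_design, homoscedastic_transform

from conftest import build_panel


def _unconstrained(name="U", lag_spec=None, weekday=True):
    return ModelSpec(
        name=name,
        lag_spec=lag_spec or LagSpec(),
        include_weekday=weekday,
        constraints=ConstraintSpec.none(),
    )


class TestOLSEquivalence:
    def test_unconstrained_equals_closed_form_least_squares(self, study_design):
        """With every constraint off, ML coefficients equal the lstsq
        solution on [intercept, dummies, lags] to 1e-8."""
        fit = fit_pooled(study_design, _unconstrained())
        A = np.column_stack(
            [
                np.ones(len(study_design)),
                study_design.dummy_matrix(),
                study_design.lag_matrix(),
            ]
        )
        beta, *_ = np.linalg.lstsq(A, study_design.response(), rcond=None)
        names = ["intercept"] + study_design.dummy_columns + study_design.lag_columns
        est = fit.params.loc[names, "estimate"].to_numpy()
        assert np.max(np.abs(est - beta)) < 1e-8

    def test_ar1_panel_recovery_vs_truth(self):
        """Unconstrained fit on a simulated AR(1) panel recovers the
        coefficient within 3 SE."""
        cfg = ml.default_config(
            seed=21, n_subjects=40, length_min=80, length_max=80, length_mode=80,
            mode_mass=1.0, mean_scale=0.0, ar_coefficients={1: 0.5},
            weekday_effects={w: 0.0 for w in WEEKDAYS}, missing_rate=0.0,
        )
        ds, _ = ml.simulate_panel(cfg)
        design = build_lag_design(
            homoscedastic_transform(ds), LagSpec(nonseasonal=(1,), multiples=0)
        )
        fit = fit_pooled(design, _unconstrained(lag_spec=LagSpec(nonseasonal=(1,), multiples=0)))
        b1, se = fit.coef("lag_1"), fit.params.loc["lag_1", "se"]
        assert abs(b1 - 0.5) < 3 * se


class TestConstraints:
    def test_constraining_never_increases_loglik(self, study_design):
        ll_free = fit_pooled(study_design, _unconstrained()).loglik
        ll_order = fit_pooled(
            study_design,
            ModelSpec(constraints=ConstraintSpec(True, True, False, False)),
        ).loglik
        ll_all = fit_pooled(study_design, model_m2()).loglik
        assert ll_order <= ll_free + 1e-6
        assert ll_all <= ll_order + 1e-6

    def test_inactive_constraint_reproduces_unconstrained(self):
        """When the data satisfy the order chains strictly, the
        constrained solution equals OLS."""
        cfg = ml.default_config(
            seed=22, n_subjects=40, length_min=60, length_max=60, length_mode=60,
            mode_mass=1.0, ar_coefficients={1: 0.55, 2: 0.2},
            weekday_effects={w: 0.0 for w in WEEKDAYS}, missing_rate=0.0,
        )
        ds, _ = ml.simulate_panel(cfg)
        spec_l = LagSpec(nonseasonal=(1, 2), multiples=0)
        design = build_lag_design(homoscedastic_transform(ds), spec_l)
        free = fit_pooled(design, _unconstrained(lag_spec=spec_l))
        cons = fit_pooled(
            design,
            ModelSpec(lag_spec=spec_l, constraints=ConstraintSpec(True, True, False, False)),
        )
        for term in ("lag_1", "lag_2"):
            assert cons.coef(term) == pytest.approx(free.coef(term), abs=1e-7)
        assert cons.diagnostics["active_constraints"] == []

    def test_order_chains_hold_and_tail_reported_active(self, study_design):
        fit = fit_pooled(study_design, model_m2())
        b = [fit.coef(f"lag_{k}") for k in (7, 14, 21, 28, 35, 42, 49, 56)]
        assert all(x >= y - 1e-12 for x, y in zip(b, b[1:]))
        assert b[-1] >= 0
        assert fit.coef("lag_1") >= fit.coef("lag_2") >= 0

    def test_one_sided_p_for_sign_constrained_lags(self, study_design):
        fit = fit_pooled(study_design, model_m2())
        assert bool(fit.params.loc["lag_1", "one_sided"])
        assert not bool(fit.params.loc["d_mon", "one_sided"])
        t1 = fit.params.loc["lag_1", "t"]
        from scipy import stats

        assert fit.params.loc["lag_1", "p"] == pytest.approx(stats.norm.sf(t1))

    def test_rank_deficient_design_raises(self, study_design):
        design2 = study_design
        frame = design2.frame.copy()
        frame["lag_1"] = frame["lag_2"]  # perfect collinearity
        bad = ml.LagDesign(frame=frame, lag_spec=design2.lag_spec, dropped={})
        with pytest.raises(RankDeficientDesignError):
            fit_pooled(bad, model_m2())

    def test_standardized_estimates_definition(self, study_design):
        fit = fit_pooled(study_design, model_m2())
        y = study_design.response()
        x = study_design.frame["lag_7"].to_numpy()
        expected = fit.coef("lag_7") * x.std() / y.std()
        assert fit.params.loc["lag_7", "std"] == pytest.approx(expected)


class TestFitIndices:
    def test_saturated_boundary(self, study_design):
        fit = fit_pooled(study_design, _unconstrained())
        assert fit.indices.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.indices.rmsea == 0.0
        assert fit.indices.cfi == 1.0

    def test_baseline_vs_itself_cfi_zero(self, study_design):
        m0 = fit_pooled(study_design, model_m0())
        assert m0.indices.cfi == 0.0
        assert m0.indices.chi2 > 0

    def test_equality_constraint_toy_discrepancy_oracle(self):
        """3-variable model (response + 2 lags, equal lag variances):
        chi2 equals n times the ML discrepancy of the closed-form
        structured covariance [[v, c], [c, v]]."""
        cfg = ml.default_config(
            seed=23, n_subjects=30, length_min=50, length_max=50, length_mode=50,
            mode_mass=1.0, ar_coefficients={1: 0.4, 2: 0.2},
            weekday_effects={w: 0.0 for w in WEEKDAYS}, missing_rate=0.0,
        )
        ds, _ = ml.simulate_panel(cfg)
        spec_l = LagSpec(nonseasonal=(1, 2), multiples=0)
        design = build_lag_design(homoscedastic_transform(ds), spec_l)
        spec = ModelSpec(
            lag_spec=spec_l,
            constraints=ConstraintSpec(False, False, True, False),
        )
        fit = fit_pooled(design, spec)
        X = design.lag_matrix()
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / len(X)
        v = (S[0, 0] + S[1, 1]) / 2.0  # closed-form MLE under equal variances
        Sigma = np.array([[v, S[0, 1]], [S[0, 1], v]])
        F = (
            np.log(np.linalg.det(Sigma))
            + np.trace(S @ np.linalg.inv(Sigma))
            - np.log(np.linalg.det(S))
            - 2
        )
        assert fit.indices.chi2 == pytest.approx(len(X) * F, rel=1e-5, abs=1e-5)
        assert fit.indices.df == 1

    def test_rmsea_ci_brackets_point_estimate(self, study_design):
        fit = fit_pooled(study_design, model_m2())
        lo, hi = fit.indices.rmsea_ci
        assert lo <= fit.indices.rmsea <= hi
        assert 0 <= fit.indices.srmr < 0.2

    def test_fit_indices_recompute_matches_stored(self, study_design):
        fit = fit_pooled(study_design, model_m2())
        base = fit_pooled(study_design, model_m0())
        idx = fit_indices(fit, fit.loglik_saturated, base)
        assert idx.chi2 == pytest.approx(fit.indices.chi2)
        assert idx.cfi == pytest.approx(fit.indices.cfi)


class TestNested:
    def test_identical_models(self, study_design):
        m2a = fit_pooled(study_design, model_m2())
        m2b = fit_pooled(study_design, model_m2())
        d, ddf, p = nested_chi2_test(m2a, m2b)
        assert (d, ddf, p) == (pytest.approx(0.0, abs=1e-9), 0, 1.0)

    def test_m3_nested_in_m2(self, study_design):
        m2 = fit_pooled(study_design, model_m2())
        m3 = fit_pooled(study_design, model_m3())
        d, ddf, p = nested_chi2_test(m3, m2)
        assert ddf == 6
        assert d > 0
        assert p < 0.001  # strong weekday effects in the generator

    def test_non_nested_rejected(self, study_design):
        m2 = fit_pooled(study_design, model_m2())
        m3 = fit_pooled(study_design, model_m3())
        with pytest.raises(ValueError, match="not nested"):
            nested_chi2_test(m2, m3)

    def test_row_mismatch_rejected(self, study_design, white_noise_panel):
        m2 = fit_pooled(study_design, model_m2())
        other_design = build_lag_design(
            homoscedastic_transform(white_noise_panel), LagSpec()
        )
        other = fit_pooled(other_design, model_m3())
        with pytest.raises(ValueError, match="identical analysis rows"):
            nested_chi2_test(other, m2)

    def test_null_calibration_of_delta_chi2(self):
        """When the restricted model is true, the chi2 difference is
        distributed as chi2 with delta-df degrees of freedom."""
        from scipy import stats

        rng_seeds = range(300)
        spec_l = LagSpec(nonseasonal=(1,), multiples=0)
        deltas = []
        for s in rng_seeds:
            cfg = ml.default_config(
                seed=1000 + s, n_subjects=5, length_min=60, length_max=60,
                length_mode=60, mode_mass=1.0, ar_coefficients={1: 0.3},
                weekday_effects={w: 0.0 for w in WEEKDAYS}, missing_rate=0.0,
                burn_in=50,
            )
            ds, _ = ml.simulate_panel(cfg)
            design = build_lag_design(homoscedastic_transform(ds), spec_l)
            full = fit_pooled(design, _unconstrained("F", spec_l, weekday=True))
            restr = fit_pooled(design, _unconstrained("R", spec_l, weekday=False))
            d, ddf, _ = nested_chi2_test(restr, full)
            assert ddf == 6
            deltas.append(d)
        pvals = stats.chi2.sf(deltas, 6)
        # QQ agreement: uniform p-values under the null
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestMultilevel:
    def test_random_intercept_recovery(self):
        """Simulated random-intercept heterogeneity is recovered by the
        mixed model within Monte-Carlo error."""
        est = []
        truth_var = []
        for s in range(4):
            cfg = ml.default_config(
                seed=40 + s, n_subjects=60, length_min=80, length_max=80,
                length_mode=80, mode_mass=1.0, ar_coefficients={1: 0.3},
                weekday_effects={w: 0.0 for w in WEEKDAYS}, missing_rate=0.0,
                mean_loc=10.0, mean_scale=0.5 / 0.7,  # intercept SD 0.5 after (1 - b)
                scale_logmean=0.0, scale_logsd=0.0,  # unit scales: raw = latent
            )
            ds, truth = ml.simulate_panel(cfg)
            intercepts = [v["intercept"] for v in truth["subjects"].values()]
            truth_var.append(np.var(intercepts))
            spec_l = LagSpec(nonseasonal=(1,), multiples=0)
            design = build_lag_design(ds, spec_l)
            spec = ModelSpec(
                name="RI", lag_spec=spec_l, include_weekday=False,
                constraints=ConstraintSpec.none(), random_effects=("intercept",),
            )
            fit = fit_multilevel(design, spec)
            est.append(fit.diagnostics["random_effect_variances"]["intercept"])
        mc_se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - np.mean(truth_var)) < max(3 * mc_se, 0.08)

    def test_degenerate_when_truth_has_no_random_effects(self, study_design):
        """On default-configuration data (one shared model) the random
        effects hit the boundary or the optimiser fails to converge —
        the elimination narrative, reported rather than raised."""
        from dataclasses import replace

        fit = fit_multilevel(study_design, replace(model_m1(), level2=()))
        boundary = fit.diagnostics["boundary_random_effects"]
        assert (not fit.converged) or len(boundary) > 0

    def test_single_subject_rejected(self):
        ds = build_panel({"A": list(np.random.default_rng(0).normal(10, 2, 30))})
        design = build_lag_design(ds, LagSpec(nonseasonal=(1,), multiples=0))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_multilevel(design, model_m1(LagSpec(nonseasonal=(1,), multiples=0)))

    def test_fit_pooled_refuses_random_specs(self, study_design):
        with pytest.raises(ValueError, match="fit_multilevel"):
            fit_pooled(study_design, model_m1())


class TestLadderSelection:
    def test_aic_prefers_m2_over_m3_across_seeds(self):
        wins = 0
        seeds = range(30, 36)
        for s in seeds:
            ds, _ = ml.simulate_panel(ml.default_config(seed=s))
            design = build_lag_design(homoscedastic_transform(ds), LagSpec())
            m2 = fit_pooled(design, model_m2())
            m3 = fit_pooled(design, model_m3())
            wins += m2.aic < m3.aic
        assert wins >= len(list(seeds)) - 1

    def test_level2_terms_estimated_and_nonsignificant(self, study_panel):
        """Gender/age carry no effect in the generator; their pooled
        coefficients must be estimable and small."""
        ds, _ = study_panel
        design = build_lag_design(homoscedastic_transform(ds), LagSpec())
        spec = ModelSpec(name="M2g", level2=("gender", "age"))
        fit = fit_pooled(design, spec, subjects=ds.subjects)
        assert {"gender", "age"} <= set(fit.params.index)
        assert abs(fit.params.loc["gender", "std"]) < 0.2
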