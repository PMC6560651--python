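"""Random-intercept occurrence models: design, quadrature, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rangehab.occupancy import (
    MODERATORS,
    OccurrenceModelSpec,
    build_design,
    build_hypothesis_set,
    compare_models,
    fit_glmm,
    fit_occurrence_model,
    likelihood_ratio_test,
    marginal_r2,
    predict_curves,
    residual_spatial_check,
)


def _simulate_glmm(rng, n_sites=41, per_site=8, beta=(-1.0, 2.0), sigma=1.0, offset=None):
    n = n_sites * per_site
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    groups = np.repeat(np.arange(n_sites), per_site)
    u = rng.normal(0.0, sigma, size=n_sites)
    eta = X @ np.asarray(beta) + u[groups]
    if offset is not None:
        eta = eta + offset
    y = (rng.uniform(size=n) < expit(eta)).astype(float)
    return X, y, groups


class TestDesign:
    def test_habitat_model_column_count(self, survey_data):
        # intercept + date + 4 habitat polys (2 cols each) + river = 11
        design = build_design(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        assert design.X.shape[1] == 11

    def test_interaction_model_column_count(self, survey_data):
        spec = OccurrenceModelSpec(
            "habitat x residence_time", habitat=True,
            moderator="residence_time", interaction=True,
        )
        # 11 + 2 moderator + (8 habitat polys + river) x 2 orders = 31
        design = build_design(survey_data, spec)
        assert design.X.shape[1] == 31

    def test_polynomial_columns_orthogonal(self, survey_data):
        design = build_design(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        i1 = design.colnames.index("emergent_veg^1")
        i2 = design.colnames.index("emergent_veg^2")
        assert abs(design.X[:, i1] @ design.X[:, i2]) < 1e-10
        assert abs(design.X[:, i1].sum()) < 1e-10  # orthogonal to the intercept

    def test_constant_predictor_rejected(self, survey_data):
        data = survey_data.copy()
        data["emergent_veg"] = 0.25
        with pytest.raises(ValueError):
            build_design(data, OccurrenceModelSpec("habitat", habitat=True))

    def test_transform_reproduces_training_matrix(self, survey_data):
        design = build_design(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        X2 = design.transform(survey_data)
        assert np.allclose(X2, design.X, atol=1e-10)


class TestHypothesisSet:
    def test_ten_models(self):
        specs = build_hypothesis_set()
        assert len(specs) == 10
        assert sum(s.interaction for s in specs) == 4
        assert sum(s.moderator is not None for s in specs) == 8

    def test_null_model_contains_only_date(self):
        null = build_hypothesis_set()[0]
        assert null.variables == ("date",)
        assert not null.habitat and null.moderator is None

    def test_interaction_specs_contain_main_effects(self, survey_data):
        for spec in build_hypothesis_set():
            if not spec.interaction:
                continue
            design = build_design(survey_data, spec)
            for main in (f"{spec.moderator}^1", f"{spec.moderator}^2", "emergent_veg^1", "river"):
                assert main in design.colnames


class TestQuadrature:
    def test_sigma_zero_limit_matches_plain_glm(self):
        # on sigma = 0 data the finite-sample ML sigma-hat has a point
        # mass at zero but is positive in some realisations; the limit
        # property is checked by pinning sigma at the boundary, where
        # the mixed model must collapse to ordinary logistic regression
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        X, y, groups = _simulate_glmm(rng, sigma=0.0)
        eps = np.exp(-6.0)
        fit = fit_glmm(X, y, groups, tol=1e-12, sigma_bounds=(eps, eps))
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.sigma_site < 0.05
        assert np.allclose(fit.beta, glm.params, atol=1e-3)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-3)

    def test_quadrature_matches_bruteforce_integration(self):
        # 3-site toy data: 25-node adaptive quadrature vs 1e5-panel
        # trapezoid integration of the marginal likelihood
        rng = np.random.default_rng(4)
        X, y, groups = _simulate_glmm(rng, n_sites=3, per_site=5, sigma=0.8)
        fit = fit_glmm(X, y, groups)
        beta, sigma = fit.beta, max(fit.sigma_site, 0.05)
        eta0 = X @ beta
        b = np.linspace(-10 * sigma, 10 * sigma, 100_001)
        ll_bf = 0.0
        for g in np.unique(groups):
            idx = groups == g
            eta = eta0[idx][:, None] + b[None, :]
            site_ll = (y[idx][:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
            dens = np.exp(site_ll) * np.exp(-0.5 * (b / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
            ll_bf += np.log(np.trapezoid(dens, b))
        assert fit._loglik_obj.loglik(beta, sigma) == pytest.approx(ll_bf, abs=1e-5)

    def test_parameter_recovery_at_design_scale(self):
        ests = []
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            X, y, groups = _simulate_glmm(rng, n_sites=41, per_site=8,
                                          beta=(-1.0, 2.0), sigma=1.0)
            fit = fit_glmm(X, y, groups)
            ests.append(fit.beta)
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(-1.0, rel=0.15)
        assert med[1] == pytest.approx(2.0, rel=0.15)

    def test_offset_rescaling_shifts_only_intercept(self):
        rng = np.random.default_rng(6)
        offset = rng.normal(size=41 * 8)
        X, y, groups = _simulate_glmm(rng, offset=offset)
        f1 = fit_glmm(X, y, groups, offset=offset, tol=1e-12)
        f2 = fit_glmm(X, y, groups, offset=offset + np.log(3.0), tol=1e-12)
        assert f2.beta[0] == pytest.approx(f1.beta[0] - np.log(3.0), abs=1e-3)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-3)
        assert f2.sigma_site == pytest.approx(f1.sigma_site, abs=1e-3)


class TestModelComparison:
    @pytest.fixture(scope="class")
    def fits(self, survey_data):
        specs = build_hypothesis_set()
        by_name = {s.name: s for s in specs}
        return {
            name: fit_occurrence_model(survey_data, by_name[name])
            for name in ("null (date only)", "habitat", "habitat + residence_time")
        }

    def test_comparison_table(self, fits):
        table = compare_models(list(fits.values()))
        assert table["delta_aic"].iloc[0] == 0.0
        assert np.allclose(table["aic"], 2 * table["n_params"] - 2 * table["loglik"])
        shuffled = compare_models(list(fits.values())[::-1])
        pd.testing.assert_frame_equal(table, shuffled)

    def test_parameter_counts_match_convention(self, fits):
        # fixed effects + 1 variance: null 3, habitat 12, additive 14
        assert fits["null (date only)"].n_params == 3
        assert fits["habitat"].n_params == 12
        assert fits["habitat + residence_time"].n_params == 14

    def test_aic_from_printed_fields(self):
        # AIC recomputed from a table row's own loglik and parameter count
        assert 2 * 20 - 2 * (-175.1) == pytest.approx(390.2)

    def test_habitat_terms_supported_on_default_truth(self, fits):
        lrt = likelihood_ratio_test(fits["habitat"], fits["null (date only)"])
        assert lrt.statistic > 0
        assert lrt.pvalue < 0.05  # generator truth has strong habitat effects


class TestLRT:
    def test_identical_models_give_zero(self, survey_data):
        fit = fit_occurrence_model(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        lrt = likelihood_ratio_test(fit, fit)
        assert lrt.statistic == 0.0 and lrt.pvalue == 1.0

    def test_statistic_arithmetic(self):
        from scipy.stats import chi2

        stat = 2 * (-10.0 - (-13.0))
        assert stat == pytest.approx(6.0)
        assert chi2.sf(stat, 2) == pytest.approx(0.0498, abs=1e-3)

    def test_non_nested_rejected(self, survey_data):
        f_cwd = fit_occurrence_model(
            survey_data, OccurrenceModelSpec("habitat + cwd", habitat=True, moderator="cwd")
        )
        f_mtcm = fit_occurrence_model(
            survey_data, OccurrenceModelSpec("habitat + mtcm", habitat=True, moderator="mtcm")
        )
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f_cwd, f_mtcm)

    def test_type_one_error_calibration(self):
        # simulate under the reduced model; adding one noise covariate
        # should reject near the nominal 5% level
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            n_sites, per_site = 41, 8
            n = n_sites * per_site
            groups = np.repeat(np.arange(n_sites), per_site)
            u = rng.normal(0.0, 0.8, size=n_sites)
            y = (rng.uniform(size=n) < expit(-0.5 + u[groups])).astype(float)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([np.ones(n), rng.normal(size=n)])
            reduced = fit_glmm(X0, y, groups, colnames=["intercept"])
            full = fit_glmm(X1, y, groups, colnames=["intercept", "noise"])
            if likelihood_ratio_test(full, reduced).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.07


class TestMarginalR2:
    def test_intercept_only_is_zero(self):
        rng = np.random.default_rng(12)
        X = np.ones((100, 1))
        groups = np.repeat(np.arange(10), 10)
        y = (rng.uniform(size=100) < 0.4).astype(float)
        fit = fit_glmm(X, y, groups)
        assert marginal_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_half(self):
        # var(fixed) = pi^2/3 and sigma = 0 gives exactly 1/2
        from rangehab.occupancy import GLMMFit

        n = 1000
        x = np.linspace(-1, 1, n)
        scale = np.sqrt((np.pi**2 / 3) / np.var(x))
        X = x[:, None] * scale
        fit = GLMMFit(
            spec=None, colnames=["x"], beta=np.array([1.0]), sigma_site=0.0,
            loglik=0.0, n_params=2, aic=0.0, marginal_r2=np.nan, converged=True,
        )
        from rangehab.occupancy import DesignMatrices, OccurrenceModelSpec

        design = DesignMatrices(
            X=X, colnames=["x"], offset=np.zeros(n), group_codes=np.zeros(n, int),
            group_labels=np.array([0]), spec=OccurrenceModelSpec("toy"), transforms={},
        )
        assert marginal_r2(fit, design) == pytest.approx(0.5, abs=1e-12)

    def test_noise_columns_barely_move_r2(self, survey_data):
        base = fit_occurrence_model(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        rng = np.random.default_rng(0)
        data = survey_data.copy()
        data["forbs"] = data["forbs"]  # same model, plus a pure-noise moderator
        data["cwd"] = rng.normal(size=len(data))
        noisy = fit_occurrence_model(
            data, OccurrenceModelSpec("habitat + cwd", habitat=True, moderator="cwd")
        )
        assert abs(noisy.marginal_r2 - base.marginal_r2) < 0.02


class TestPredictions:
    @pytest.fixture(scope="class")
    def habitat_fit(self, survey_data):
        return fit_occurrence_model(survey_data, OccurrenceModelSpec("habitat", habitat=True))

    def test_probabilities_bounded(self, habitat_fit):
        curves = predict_curves(habitat_fit, "emergent_veg")
        for col in ("probability", "ci_low", "ci_high"):
            assert curves[col].between(0, 1).all()
        assert (curves["ci_low"] <= curves["probability"]).all()
        assert (curves["probability"] <= curves["ci_high"]).all()

    def test_mean_point_prediction_definition(self, habitat_fit, survey_data):
        design = habitat_fit.design
        focal = "trees_bushes"
        curves = predict_curves(habitat_fit, focal, n_grid=3)
        new = pd.DataFrame({v: [survey_data[v].mean()] for v in design.spec.variables})
        new[focal] = curves[focal].iloc[1]
        lp = (design.transform(new) @ habitat_fit.beta)[0] + np.mean(design.offset)
        assert curves["probability"].iloc[1] == pytest.approx(expit(lp), abs=1e-10)

    def test_intervals_widen_toward_range_edges(self, habitat_fit):
        curves = predict_curves(habitat_fit, "emergent_veg", n_grid=41)
        width = curves["ci_high"] - curves["ci_low"]
        mid = width.iloc[15:26].min()
        assert width.iloc[0] > mid and width.iloc[-1] > mid

    def test_moderator_strata_curves(self, survey_data):
        spec = OccurrenceModelSpec(
            "habitat x residence_time", habitat=True,
            moderator="residence_time", interaction=True,
        )
        fit = fit_occurrence_model(survey_data, spec)
        curves = predict_curves(fit, "emergent_veg", moderator_values=[5.0, 35.0], n_grid=11)
        assert set(curves["residence_time"]) == {5.0, 35.0}
        assert len(curves) == 22

    def test_unknown_focal_rejected(self, habitat_fit):
        with pytest.raises(ValueError):
            predict_curves(habitat_fit, "cwd")


class TestSpatialCheck:
    def test_independent_residuals_stay_inside_envelope(self, survey_data):
        fit = fit_occurrence_model(survey_data, OccurrenceModelSpec("habitat", habitat=True))
        coords = survey_data[["x", "y"]].to_numpy()
        out = residual_spatial_check(fit, coords, n_perm=499, seed=1)
        assert (~out["outside"]).mean() >= 0.9

    def test_constructed_spatial_signal_detected(self, survey_data):
        # presence replaced by a pure east-west step: a date-only model
        # cannot absorb it, so short-range correlation must flag
        data = survey_data.copy()
        data["presence"] = (data["x"] > data["x"].median()).astype(int)
        fit = fit_occurrence_model(data, OccurrenceModelSpec("null (date only)"))
        out = residual_spatial_check(fit, data[["x", "y"]].to_numpy(), n_perm=499, seed=1)
        assert bool(out["outside"].iloc[0])
        assert out["moran"].iloc[0] > 0

    def test_envelope_deterministic_under_seed(self, survey_data):
        fit = fit_occurrence_model(survey_data, OccurrenceModelSpec("null (date only)"))
        coords = survey_data[["x", "y"]].to_numpy()
        a = residual_spatial_check(fit, coords, n_perm=199, seed=7)
        b = residual_spatial_check(fit, coords, n_perm=199, seed=7)
        pd.testing.assert_frame_equal(a, b)
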