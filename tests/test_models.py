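"""Model fitting: OLS oracles, REML against brute force and statsmodels, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from springlayer.errors import EstimationError, UsageError
from springlayer.models import (
    ModelSpec,
    fit_combined,
    fit_location_specific,
    predict_compliance,
    reml_objective,
    significance_stars,
)
from springlayer.synthetic import GeneratorConfig, generate_study
from springlayer.preprocess import build_feature_table

from conftest import SMALL_SITES


def _features(t_m, t_f, y, sites=None, subjects=None):
    n = len(y)
    return pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else [f"S{i}" for i in range(n)],
            "site": sites if sites is not None else ["LA_A"] * n,
            "t_muscle_mm": t_m,
            "t_fat_mm": t_f,
            "compliance_mm3_per_N": y,
        }
    )


def brute_force_reml(s2_s, s2_l, s2_e, X, Z_s, Z_l, y):
    """Dense-matrix restricted log-likelihood, independent of the package path."""
    n, p = X.shape
    V = s2_e * np.eye(n) + s2_s * Z_s @ Z_s.T + s2_l * Z_l @ Z_l.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


def _design_matrices(features):
    X = features[["t_muscle_mm", "t_fat_mm"]].to_numpy(float)
    y = features["compliance_mm3_per_N"].to_numpy(float)
    Z_s = pd.get_dummies(features["subject_id"]).to_numpy(float)
    Z_l = pd.get_dummies(features["site"]).to_numpy(float)
    return X, Z_s, Z_l, y


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.0005, "***"), (0.03, "*"), (0.005, "**"),
         (0.05, ""), (0.001, "**"), (0.2, ""), (0.0, "***"), (1.0, "")],
    )
    def test_half_open_thresholds(self, p, label):
        assert significance_stars(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            significance_stars(p)


class TestLocationSpecific:
    def test_exact_recovery_zero_residual(self):
        rng = np.random.default_rng(0)
        t_m, t_f = rng.uniform(10, 50, 12), rng.uniform(3, 20, 12)
        y = 3.77 * t_m + 18.10 * t_f
        fit = fit_location_specific(_features(t_m, t_f, y), ModelSpec("physics", "LA_A"))
        assert fit.coef["muscle"] == pytest.approx(3.77, abs=1e-9)
        assert fit.coef["fat"] == pytest.approx(18.10, abs=1e-9)
        assert "intercept" not in fit.coef

    @pytest.mark.parametrize("family", ["physics", "conventional"])
    def test_matches_normal_equations_oracle(self, family):
        """Coefficients and SEs equal an independently coded (X'X)^-1 X'y solve."""
        rng = np.random.default_rng(42)
        n = 30
        t_m, t_f = rng.uniform(10, 50, n), rng.uniform(3, 20, n)
        y = 4.0 * t_m + 15.0 * t_f + rng.normal(0, 30, n)
        fit = fit_location_specific(_features(t_m, t_f, y), ModelSpec(family, "LA_A"))
        X = np.column_stack([t_m, t_f])
        names = ["muscle", "fat"]
        if family == "conventional":
            X = np.column_stack([np.ones(n), X])
            names = ["intercept", *names]
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta
        cov = (resid @ resid) / (n - X.shape[1]) * np.linalg.inv(X.T @ X)
        for j, name in enumerate(names):
            assert fit.coef[name] == pytest.approx(beta[j], abs=1e-10)
            assert fit.se[name] == pytest.approx(np.sqrt(cov[j, j]), abs=1e-10)

    def test_zero_residual_df_rejected(self):
        fit_input = _features([10.0, 20.0], [5.0, 8.0], [100.0, 200.0])
        with pytest.raises(EstimationError, match="degrees of freedom"):
            fit_location_specific(fit_input, ModelSpec("physics", "LA_A"))

    def test_rank_deficient_design_rejected(self):
        t_m = np.array([10.0, 20, 30, 40])
        with pytest.raises(EstimationError, match="rank"):
            fit_location_specific(
                _features(t_m, 0.5 * t_m, t_m * 5.0), ModelSpec("physics", "LA_A")
            )

    def test_stars_consistent_with_p(self, small_features):
        for site in SMALL_SITES:
            fit = fit_location_specific(small_features, ModelSpec("physics", site))
            for term, p in fit.p.items():
                assert fit.stars[term] == significance_stars(p)


class TestRemlObjective:
    @pytest.fixture(scope="class")
    def small_mixed(self):
        cfg = GeneratorConfig(
            n_subjects=6, sites=SMALL_SITES[:3], n_trace_points=10, seed=21
        )
        trials, _ = generate_study(cfg)
        return _design_matrices(build_feature_table(trials))

    def test_closed_form_residual_only_limit(self, small_mixed):
        """With all variance residual, equals the weighted-OLS restricted likelihood."""
        X, Z_s, Z_l, y = small_mixed
        n, p = X.shape
        s2 = 1800.0
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        closed = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2)
            + np.linalg.slogdet(X.T @ X)[1]
            + rss / s2
        )
        got = reml_objective((0.0, 0.0, s2), X, Z_s, Z_l, y)
        assert got == pytest.approx(closed, abs=1e-8)

    def test_matches_dense_brute_force(self, small_mixed):
        X, Z_s, Z_l, y = small_mixed
        for comps in [(900.0, 400.0, 2000.0), (10.0, 5000.0, 100.0), (0.0, 50.0, 900.0)]:
            assert reml_objective(comps, X, Z_s, Z_l, y) == pytest.approx(
                brute_force_reml(*comps, X, Z_s, Z_l, y), abs=1e-7
            )

    def test_scaling_identity(self, small_mixed):
        """Scaling y and all SDs by c shifts the objective by -(n-p) log c."""
        X, Z_s, Z_l, y = small_mixed
        n, p = X.shape
        comps = (900.0, 400.0, 2000.0)
        base = reml_objective(comps, X, Z_s, Z_l, y)
        c = 3.0
        scaled = reml_objective(
            tuple(v * c**2 for v in comps), X, Z_s, Z_l, y * c
        )
        assert scaled == pytest.approx(base - (n - p) * np.log(c), abs=1e-8)

    def test_negative_variance_rejected(self, small_mixed):
        X, Z_s, Z_l, y = small_mixed
        with pytest.raises(ValueError):
            reml_objective((-1.0, 0.0, 100.0), X, Z_s, Z_l, y)

    def test_zero_residual_variance_singular(self, small_mixed):
        X, Z_s, Z_l, y = small_mixed
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            reml_objective((100.0, 100.0, 0.0), X, Z_s, Z_l, y)


class TestFitCombined:
    def test_degenerate_no_random_effects_equals_ols(self, noise_free_config):
        """Data with zero subject/location variance: mixed fit collapses to OLS."""
        import dataclasses

        cfg = dataclasses.replace(noise_free_config, sigma_resid=25.0, seed=13)
        trials, _ = generate_study(cfg)
        feat = build_feature_table(trials)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_combined(feat, ModelSpec("physics", "combined"))
        X, _, _, y = _design_matrices(feat)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.coef["muscle"] == pytest.approx(beta_ols[0], rel=1e-6)
        assert fit.coef["fat"] == pytest.approx(beta_ols[1], rel=1e-6)
        vc = fit.variance_components
        assert vc["sigma2_subject"] < 1e-4 * vc["sigma2_resid"]
        assert vc["sigma2_location"] < 1e-4 * vc["sigma2_resid"]

    def test_optimum_beats_dense_grid(self):
        """REML optimum dominates a dense grid of the restricted likelihood."""
        cfg = GeneratorConfig(
            n_subjects=6, sites=SMALL_SITES[:3], n_trace_points=10, seed=33
        )
        trials, _ = generate_study(cfg)
        feat = build_feature_table(trials)
        fit = fit_combined(feat, ModelSpec("physics", "combined"))
        X, Z_s, Z_l, y = _design_matrices(feat)
        best_grid = -np.inf
        s2_grid = np.geomspace(1e-1, 1e5, 13)
        for s2_s in np.concatenate([[0.0], s2_grid]):
            for s2_l in np.concatenate([[0.0], s2_grid]):
                for s2_e in s2_grid:
                    best_grid = max(
                        best_grid, brute_force_reml(s2_s, s2_l, s2_e, X, Z_s, Z_l, y)
                    )
        assert fit.reml_value >= best_grid - 1e-6

    def test_matches_statsmodels_mixedlm(self, small_features):
        """Independent route: statsmodels MixedLM with crossed variance components."""
        import statsmodels.formula.api as smf

        fit = fit_combined(small_features, ModelSpec("physics", "combined"))
        df = small_features.rename(
            columns={"t_muscle_mm": "tm", "t_fat_mm": "tf", "compliance_mm3_per_N": "y"}
        ).assign(grp=1)
        sm_fit = smf.mixedlm(
            "y ~ 0 + tm + tf",
            df,
            groups="grp",
            vc_formula={"subject": "0 + C(subject_id)", "site": "0 + C(site)"},
        ).fit(reml=True)
        assert fit.coef["muscle"] == pytest.approx(sm_fit.fe_params["tm"], rel=1e-4)
        assert fit.coef["fat"] == pytest.approx(sm_fit.fe_params["tf"], rel=1e-4)
        assert fit.variance_components["sigma2_resid"] == pytest.approx(
            sm_fit.scale, rel=1e-3
        )

    def test_objective_never_below_start(self, combined_physics_fit):
        """Optimizer sanity: returned optimum >= objective at every start."""
        for t in combined_physics_fit.optimizer_info["starts"]:
            assert combined_physics_fit.reml_value >= t["loglik"] - 1e-9

    def test_reml_value_consistent_with_public_objective(
        self, combined_physics_fit, small_features
    ):
        X, Z_s, Z_l, y = _design_matrices(small_features)
        vc = combined_physics_fit.variance_components
        val = reml_objective(
            (vc["sigma2_subject"], vc["sigma2_location"], vc["sigma2_resid"]),
            X, Z_s, Z_l, y,
        )
        assert val == pytest.approx(combined_physics_fit.reml_value, abs=1e-6)

    def test_blups_shrunken_and_centered(self, combined_physics_fit):
        u = np.array(list(combined_physics_fit.random_effects["subject"].values()))
        v = np.array(list(combined_physics_fit.random_effects["location"].values()))
        s_u = combined_physics_fit.variance_components["sigma2_subject"]
        # BLUP variance never exceeds the estimated component variance
        assert u.var() <= s_u * 1.5 + 1e-9
        assert len(v) == len(SMALL_SITES)

    def test_too_few_groups_rejected(self):
        feat = _features(
            [10.0, 20, 30, 40], [5.0, 8, 9, 12], [250.0, 300, 350, 400],
            sites=["LA_A"] * 4, subjects=["S1", "S2", "S3", "S4"],
        )
        with pytest.raises(EstimationError, match="sites"):
            fit_combined(feat, ModelSpec("physics", "combined"))


class TestPrediction:
    def test_hand_checked_fixed_prediction(self, combined_physics_fit):
        fit = combined_physics_fit
        fit_mod = fit.__class__(**{**fit.__dict__})
        fit_mod.coef = {"muscle": 3.77, "fat": 18.10}
        rows = pd.DataFrame({"t_muscle_mm": [10.0], "t_fat_mm": [2.0]})
        pred = predict_compliance(fit_mod, rows, mode="fixed_only")
        assert pred[0] == pytest.approx(73.9, abs=1e-9)  # 37.7 + 36.2

    def test_origin_constraint(self, combined_physics_fit):
        rows = pd.DataFrame({"t_muscle_mm": [0.0], "t_fat_mm": [0.0]})
        assert predict_compliance(combined_physics_fit, rows, "fixed_only")[0] == 0.0

    def test_conditional_equals_fixed_when_blups_zero(self, combined_physics_fit):
        rows = pd.DataFrame(
            {
                "t_muscle_mm": [25.0],
                "t_fat_mm": [8.0],
                "subject_id": ["UNSEEN"],
                "site": ["LL_A"],  # not in SMALL_SITES study
            }
        )
        fixed = predict_compliance(combined_physics_fit, rows, "fixed_only")
        cond = predict_compliance(combined_physics_fit, rows, "conditional")
        np.testing.assert_allclose(fixed, cond)

    def test_conditional_on_location_specific_rejected(self, small_features):
        fit = fit_location_specific(small_features, ModelSpec("physics", "LA_A"))
        rows = small_features.head(3)
        with pytest.raises(UsageError, match="conditional"):
            predict_compliance(fit, rows, "conditional")


@settings(max_examples=10, deadline=None, derandomize=True)
@given(c=st.floats(0.2, 5.0))
def test_scale_equivariance_of_coefficients(c):
    """Thickness * c => coefficients / c, predictions unchanged."""
    rng = np.random.default_rng(77)
    n = 25
    t_m, t_f = rng.uniform(10, 50, n), rng.uniform(3, 20, n)
    y = 4.0 * t_m + 15.0 * t_f + rng.normal(0, 20, n)
    base = fit_location_specific(_features(t_m, t_f, y), ModelSpec("physics", "LA_A"))
    scaled = fit_location_specific(
        _features(t_m * c, t_f * c, y), ModelSpec("physics", "LA_A")
    )
    assert scaled.coef["muscle"] == pytest.approx(base.coef["muscle"] / c, rel=1e-9)
    assert scaled.coef["fat"] == pytest.approx(base.coef["fat"] / c, rel=1e-9)
    rows = pd.DataFrame({"t_muscle_mm": t_m * c, "t_fat_mm": t_f * c})
    rows_base = pd.DataFrame({"t_muscle_mm": t_m, "t_fat_mm": t_f})
    np.testing.assert_allclose(
        predict_compliance(scaled, rows),
        predict_compliance(base, rows_base),
        rtol=1e-9,
    )
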