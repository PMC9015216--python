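import numpy as np
import pandas as pd
import pytest

from morphdispersal import (
    fit_brown_proportion_glm,
    fit_crossed_lmm,
    fit_dispersal_lmm,
    marginal_effects,
    satterthwaite_df,
    simulate_population,
    SimulationParams,
)


def _crossed_data(seed=1, n=120, sd1=1.5, sd2=0.8, resid=1.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "g1": rng.integers(0, 8, n).astype(str),
            "g2": rng.integers(0, 10, n).astype(str),
        }
    )
    e1 = dict(zip(map(str, range(8)), rng.normal(0, sd1, 8)))
    e2 = dict(zip(map(str, range(10)), rng.normal(0, sd2, 10)))
    df["y"] = (
        1.0 + 2.0 * df["x"] + df["g1"].map(e1) + df["g2"].map(e2)
        + rng.normal(0, resid, n)
    )
    return df


class TestCrossedREML:
    def test_no_random_effects_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"Intercept": 1.0, "x": rng.normal(size=40)})
        y = 2.0 + 0.5 * X["x"] + rng.normal(size=40)
        fit = fit_crossed_lmm(y, X, random_factors={})
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-10)
        c = np.array([0.0, 1.0])
        assert satterthwaite_df(fit, c) == pytest.approx(38.0)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: the same crossed-intercepts REML fit via
        statsmodels MixedLM's variance-component formulation."""
        import statsmodels.formula.api as smf

        df = _crossed_data()
        X = pd.DataFrame({"Intercept": 1.0, "x": df["x"]})
        mine = fit_crossed_lmm(
            df["y"], X, random_factors={"g1": df["g1"], "g2": df["g2"]}
        )
        sm_fit = smf.mixedlm(
            "y ~ x",
            df,
            groups=np.ones(len(df)),
            vc_formula={"g1": "0 + C(g1)", "g2": "0 + C(g2)"},
            re_formula="0",
        ).fit(reml=True, method="lbfgs")
        assert np.allclose(mine.beta.to_numpy(), sm_fit.fe_params.values, atol=1e-4)
        assert np.allclose(
            np.sqrt(np.diag(mine.cov_beta)), sm_fit.bse_fe.values, rtol=5e-3
        )
        assert mine.sigma2_resid == pytest.approx(sm_fit.scale, rel=5e-3)
        assert mine.loglik == pytest.approx(sm_fit.llf, abs=1e-3)
        # tighter check: our optimum is at least as good as the oracle's
        assert mine.loglik >= sm_fit.llf - 1e-6

    def test_fixed_effects_invariant_to_random_factor_order(self):
        df = _crossed_data(seed=5)
        X = pd.DataFrame({"Intercept": 1.0, "x": df["x"]})
        f1 = fit_crossed_lmm(df["y"], X, random_factors={"g1": df["g1"], "g2": df["g2"]})
        f2 = fit_crossed_lmm(df["y"], X, random_factors={"g2": df["g2"], "g1": df["g1"]})
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        assert f1.variance_components["g1"]["variance"] == pytest.approx(
            f2.variance_components["g1"]["variance"], abs=1e-6
        )


class TestSatterthwaite:
    def test_welch_two_sample_closed_form(self):
        """A two-group heteroscedastic mean difference written as a
        variance-component model must reproduce the Welch-Satterthwaite df."""
        rng = np.random.default_rng(3)
        n1, n2 = 14, 9
        y1 = rng.normal(0.0, 1.0, n1)
        y2 = rng.normal(2.0, 3.0, n2)
        y = np.concatenate([y1, y2])
        g2 = np.concatenate([np.zeros(n1), np.ones(n2)])
        X = pd.DataFrame({"Intercept": 1.0, "group2": g2})
        # per-observation extra variance for group 2 rows
        Z = np.zeros((n1 + n2, n2))
        Z[n1:, :] = np.eye(n2)
        fit = fit_crossed_lmm(y, X, z_matrices={"extra2": Z})
        s1, s2 = y1.var(ddof=1), y2.var(ddof=1)
        assert s2 > s1  # construction is interior, not at the boundary
        assert fit.sigma2_resid == pytest.approx(s1, rel=1e-4)
        assert fit.variance_components["extra2"]["variance"] == pytest.approx(
            s2 - s1, rel=1e-3
        )
        v1, v2 = s1 / n1, s2 / n2
        welch = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        df = satterthwaite_df(fit, np.array([0.0, 1.0]))
        assert df == pytest.approx(welch, rel=0.01)

    def test_one_way_limit_intercept_df_near_groups_minus_one(self):
        rng = np.random.default_rng(4)
        g, k = 8, 10
        groups = np.repeat(np.arange(g), k)
        y = rng.normal(0, 10, g)[groups] + rng.normal(0, 1, g * k)
        X = pd.DataFrame({"Intercept": np.ones(g * k)})
        fit = fit_crossed_lmm(y, X, random_factors={"grp": groups})
        df = satterthwaite_df(fit, np.array([1.0]))
        assert df == pytest.approx(g - 1, rel=0.15)

    def test_df_reaches_residual_df_when_variance_hits_the_boundary(self):
        """In a balanced one-way layout the intercept df sits near g-1 while
        the group component is present and jumps to the residual df n-p once
        the REML estimate lands on the zero boundary (the v -> 0 limit)."""
        g, k = 8, 10
        groups = np.repeat(np.arange(g), k)
        rng = np.random.default_rng(1)
        x = rng.normal(size=g * k)
        resid = rng.normal(0, 1, g * k)
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        # group variance present: df anchored near g - 1, far below n - p
        y_with = 1.0 + 0.5 * x + rng.normal(0, 3, g)[groups] + resid
        fit_with = fit_crossed_lmm(y_with, X, random_factors={"grp": groups})
        df_with = satterthwaite_df(fit_with, np.array([1.0, 0.0]))
        assert df_with == pytest.approx(g - 1, rel=0.25)
        # no group variance in truth: estimate hits 0, df becomes n - p
        y_null = 1.0 + 0.5 * x + resid
        fit_null = fit_crossed_lmm(y_null, X, random_factors={"grp": groups})
        assert fit_null.variance_components["grp"]["variance"] == 0.0
        df_null = satterthwaite_df(fit_null, np.array([1.0, 0.0]))
        assert df_null == pytest.approx(g * k - 2, abs=1e-3)
        assert df_with < df_null


class TestDispersalLmm:
    def test_reference_flip_negates_interaction(self, small_params):
        bundle = simulate_population(small_params)
        rec = bundle.recruits.dropna(subset=["morph"])
        fit = fit_dispersal_lmm(rec, analysis_set="all-ages")
        flipped = rec.copy()
        flipped["morph"] = flipped["morph"].map({"gray": "brown", "brown": "gray"})
        fit_f = fit_dispersal_lmm(flipped, analysis_set="all-ages")
        assert fit_f.beta["anomaly_c:morph_brown"] == pytest.approx(
            -fit.beta["anomaly_c:morph_brown"], rel=1e-4
        )

    def test_analysis_sets_and_listwise_counts(self, small_params):
        bundle = simulate_population(small_params)
        rec = bundle.recruits.copy()
        rec.loc[rec.index[:3], "body_mass_g"] = np.nan
        n_complete = rec.dropna(
            subset=["morph", "body_mass_g", "dispersal_km"]
        ).shape[0]
        fit_all = fit_dispersal_lmm(rec, analysis_set="all-ages")
        assert fit_all.n_obs == n_complete
        fit_one = fit_dispersal_lmm(rec, analysis_set="one-year-olds")
        n_one = rec.dropna(subset=["morph", "body_mass_g"]).pipe(
            lambda d: (d["age_at_recruitment"].astype(str) == "1").sum()
        )
        assert fit_one.n_obs == n_one
        assert "age_at_recruitment" in fit_all.terms
        assert "age_at_recruitment" not in fit_one.terms

    def test_age_term_is_a_joint_two_df_test(self, small_params):
        bundle = simulate_population(small_params)
        fit = fit_dispersal_lmm(bundle.recruits.dropna(subset=["morph"]))
        test = fit.term_test("age_at_recruitment")
        assert test["num_df"] == 2
        assert test["den_df"] > 2
        assert 0 <= test["p"] <= 1


class TestMarginalEffects:
    def test_slope_difference_equals_interaction_coefficient(self, small_params):
        bundle = simulate_population(small_params)
        fit = fit_dispersal_lmm(bundle.recruits.dropna(subset=["morph"]))
        grid = np.array([-2.0, 2.0])
        me = marginal_effects(fit, grid)
        slope = {
            m: (
                me[(me["morph"] == m) & (me["anomaly_c"] == 2.0)]["predicted_km"].item()
                - me[(me["morph"] == m) & (me["anomaly_c"] == -2.0)]["predicted_km"].item()
            )
            / 4.0
            for m in ("gray", "brown")
        }
        assert slope["brown"] - slope["gray"] == pytest.approx(
            fit.beta["anomaly_c:morph_brown"], abs=1e-9
        )

    def test_ci_narrower_at_center_and_extrapolation_flagged(self, small_params):
        bundle = simulate_population(small_params)
        fit = fit_dispersal_lmm(bundle.recruits.dropna(subset=["morph"]))
        lo, hi = fit.anomaly_range
        center = bundle.recruits["anomaly_c"].mean()
        me = marginal_effects(fit, [center, hi + 5.0], morph_levels=["gray"])
        width = me["ci_high_km"] - me["ci_low_km"]
        assert width.iloc[0] < width.iloc[1]
        assert not me["extrapolated"].iloc[0]
        assert me["extrapolated"].iloc[1]


class TestBrownProportionGlm:
    def test_flat_proportions_give_zero_slope(self):
        yearly = pd.DataFrame(
            {
                "n_brown": [3] * 10,
                "n_total": [10] * 10,
                "anomaly_c": np.linspace(-3, 3, 10),
            }
        )
        fit = fit_brown_proportion_glm(yearly)
        assert fit.slope_estimate == pytest.approx(0.0, abs=1e-8)
        assert fit.n_years == 10

    def test_recovers_known_slope_within_two_se(self):
        rng = np.random.default_rng(8)
        slope, intercept = 0.6, -0.8
        anomaly = rng.normal(0, 2, 35)
        n_total = rng.integers(3, 12, 35)
        p = 1 / (1 + np.exp(-(intercept + slope * anomaly)))
        yearly = pd.DataFrame(
            {
                "n_brown": rng.binomial(n_total, p),
                "n_total": n_total,
                "anomaly_c": anomaly,
            }
        )
        fit = fit_brown_proportion_glm(yearly)
        assert abs(fit.slope_estimate - slope) < 2 * fit.slope_se

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            anomaly = rng.normal(0, 2, 35)
            n_total = rng.integers(2, 10, 35)
            yearly = pd.DataFrame(
                {
                    "n_brown": rng.binomial(n_total, 0.3),
                    "n_total": n_total,
                    "anomaly_c": anomaly,
                }
            )
            if fit_brown_proportion_glm(yearly).p < 0.05 - 1e-12:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09

    def test_degenerate_inputs_rejected(self):
        one_year = pd.DataFrame({"n_brown": [1], "n_total": [4], "anomaly_c": [0.0]})
        with pytest.raises(ValueError):
            fit_brown_proportion_glm(one_year)
        all_gray = pd.DataFrame(
            {"n_brown": [0, 0, 0], "n_total": [5, 6, 7], "anomaly_c": [-1, 0, 1]}
        )
        with pytest.raises(ValueError, match="one morph"):
            fit_brown_proportion_glm(all_gray)
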