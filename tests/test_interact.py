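import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coevoscan import interact, simgen
from coevoscan.interact import (
    average_marginal_effects,
    encode,
    fit_interaction,
    lrt_interaction,
    studentized_outlier_filter,
    three_way_sex,
)


class TestEncode:
    def test_genotypic_indicators(self):
        enc = encode([0, 1, 2], "genotypic")
        np.testing.assert_array_equal(enc.columns["g_het"], [0, 1, 0])
        np.testing.assert_array_equal(enc.columns["g_homalt"], [0, 0, 1])

    def test_additive_passthrough_and_constant_flag(self):
        enc = encode([0, 0, 0], "additive")
        assert enc.constant
        np.testing.assert_array_equal(enc.columns["g"], 0.0)

    def test_missing_propagates(self):
        enc = encode([0, -1, 2], "genotypic")
        assert enc.columns.iloc[1].isna().all()

    def test_unknown_mode_is_error(self):
        with pytest.raises(ValueError, match="encoding"):
            encode([0, 1], "dominant")


def _sim_xy(rng, n=300, beta_int=0.0, family="gaussian"):
    g1 = rng.binomial(2, 0.4, n)
    g2 = rng.binomial(2, 0.3, n)
    cov = rng.standard_normal((n, 3))
    eta = 0.3 * g1 - 0.2 * g2 + beta_int * g1 * g2 + cov @ [0.2, -0.1, 0.3]
    if family == "gaussian":
        y = eta + rng.standard_normal(n)
    else:
        p = 1 / (1 + np.exp(-(eta - eta.mean())))
        y = rng.binomial(1, p)
    return y, g1, g2, cov


class TestFitInteraction:
    def test_exact_recovery_of_noiseless_product(self, rng):
        g1 = rng.integers(0, 3, 100)
        g2 = rng.integers(0, 3, 100)
        y = (g1 * g2).astype(float)
        fit = fit_interaction(y, g1, g2)
        assert fit.params["g1:g2"] == pytest.approx(1.0, abs=1e-10)
        resid = y - fit.design.to_numpy() @ fit.params.to_numpy()
        assert np.abs(resid).max() < 1e-10

    def test_gaussian_matches_normal_equations(self, rng):
        y, g1, g2, cov = _sim_xy(rng, beta_int=0.2)
        fit = fit_interaction(y, g1, g2, covariates=cov)
        X = fit.design.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ fit.y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_wald_and_lrt_agree_directionally(self, rng):
        y, g1, g2, cov = _sim_xy(rng, n=500, beta_int=0.4)
        fit = fit_interaction(y, g1, g2, covariates=cov)
        assert fit.wald_p["g1:g2"] < 0.01
        assert fit.lrt_p < 0.01
        assert fit.lrt_df == 1

    def test_listwise_deletion_reported_via_n(self, rng):
        y, g1, g2, cov = _sim_xy(rng, n=100)
        g1 = g1.astype(float)
        g1[:7] = -1  # missing sentinel
        fit = fit_interaction(y, g1, g2, covariates=cov)
        assert fit.n == 93

    def test_collinear_design_is_error(self, rng):
        y, g1, _, _ = _sim_xy(rng, n=80)
        with pytest.raises(ValueError, match="collinear"):
            fit_interaction(y, g1, g1.copy(), covariates=None)

    def test_standardized_outcome_preserves_inference(self, rng):
        y, g1, g2, cov = _sim_xy(rng, n=400, beta_int=0.3)
        raw = fit_interaction(y, g1, g2, covariates=cov)
        std = fit_interaction(y, g1, g2, covariates=cov, standardize_y=True)
        assert std.wald_p["g1:g2"] == pytest.approx(raw.wald_p["g1:g2"], abs=1e-10)
        scale = np.std(y, ddof=1)
        assert std.params["g1:g2"] == pytest.approx(
            raw.params["g1:g2"] / scale, rel=1e-9
        )

    def test_genotypic_loglik_at_least_additive(self, rng):
        y, g1, g2, cov = _sim_xy(rng, n=400, beta_int=0.3)
        add = fit_interaction(y, g1, g2, covariates=cov)
        gen = fit_interaction(
            y, g1, g2, covariates=cov, encoding1="genotypic", encoding2="genotypic"
        )
        assert gen.llf >= add.llf - 1e-8


class TestLrt:
    def test_identical_models_give_zero_and_p_one(self, rng):
        y, g1, g2, cov = _sim_xy(rng)
        fit = fit_interaction(y, g1, g2, covariates=cov)
        stat, df, p = lrt_interaction(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_genotypic_by_additive_drops_two_params(self, rng):
        y, g1, g2, cov = _sim_xy(rng)
        fit = fit_interaction(y, g1, g2, covariates=cov, encoding1="genotypic")
        assert fit.lrt_df == 2
        both = fit_interaction(
            y, g1, g2, covariates=cov, encoding1="genotypic", encoding2="genotypic"
        )
        assert both.lrt_df == 4

    def test_matches_independent_deviance_difference(self, rng):
        y, g1, g2, cov = _sim_xy(rng, n=600, beta_int=0.3, family="binomial")
        fit = fit_interaction(y, g1, g2, covariates=cov, family="binomial")
        X = fit.design
        full = sm.GLM(fit.y, X, family=sm.families.Binomial()).fit()
        red = sm.GLM(
            fit.y, X.drop(columns=["g1:g2"]), family=sm.families.Binomial()
        ).fit()
        assert fit.lrt_stat == pytest.approx(red.deviance - full.deviance, abs=1e-8)

    def test_non_nested_is_error(self, rng):
        y, g1, g2, cov = _sim_xy(rng)
        a = fit_interaction(y, g1, g2, covariates=cov)
        b = fit_interaction(y, g1, g2, covariates=None)
        with pytest.raises(ValueError):
            lrt_interaction(b, a)


class TestThreeWay:
    def test_pure_sex_shift_gives_zero_three_way_terms(self, rng):
        n = 200
        g1 = rng.integers(0, 3, n)
        g2 = rng.integers(0, 3, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        y = 0.5 * g1 + 1.0 * (sex == "male")  # no interactions at all
        fit = three_way_sex(y, g1, g2, sex)
        for term in fit.interaction_terms:
            assert fit.params[term] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["sex_male"] == pytest.approx(1.0, abs=1e-8)

    def test_single_sex_is_error(self, rng):
        n = 50
        g1 = rng.integers(0, 3, n)
        with pytest.raises(ValueError):
            three_way_sex(rng.standard_normal(n), g1, g1, np.repeat("male", n))

    def test_detects_opposite_sign_interaction(self):
        cfg = simgen.SimConfig(
            seed=21, n_admixed_female=1000, n_admixed_male=1000, build_track=False
        )
        cohort = simgen.simulate_cohort(cfg)
        expr = simgen.ExpressionConfig(
            beta_interaction_male=0.3, beta_interaction_female=-0.3
        )
        y, cov = simgen.simulate_expression(cohort, expr, seed=2)
        d1, d2 = cohort.focal_dosages()
        sex = cohort.admixed_panel().table["sex"].to_numpy()
        fit = three_way_sex(y.to_numpy(), d1, d2, sex, covariates=cov.to_numpy())
        assert fit.lrt_df == 1
        assert fit.lrt_p < 0.01


class TestAme:
    def _binomial_fit(self, rng, n=800):
        g1 = rng.binomial(2, 0.4, n)
        g2 = rng.binomial(2, 0.3, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        eta = -1.2 + 0.4 * g2 + 0.3 * g1 - 0.25 * g1 * g2 + 0.2 * (sex == "male")
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = fit_interaction(
            y, g1, g2, family="binomial", encoding1="genotypic", sex=sex
        )
        return fit, g1, sex

    def test_matches_finite_difference_of_probabilities(self, rng):
        fit, g1, sex = self._binomial_fit(rng)
        ame = average_marginal_effects(fit, focal="g2")
        X = fit.design.to_numpy()
        theta = fit.params.to_numpy()
        h = 1e-6
        cols = list(fit.design.columns)
        dX = np.zeros_like(X)
        for k, c in enumerate(cols):
            factors = c.split(":")
            if "g2" in factors:
                prod = np.ones(len(X))
                for f in factors:
                    if f != "g2":
                        prod *= fit.design[f].to_numpy()
                dX[:, k] = prod
        p_hi = 1 / (1 + np.exp(-(X + h * dX) @ theta))
        p_lo = 1 / (1 + np.exp(-(X - h * dX) @ theta))
        fd = ((p_hi - p_lo) / (2 * h)).mean()
        assert ame["ame"].iloc[0] == pytest.approx(fd, abs=1e-6)

    def test_gaussian_ame_equals_linear_derivative(self, rng):
        n = 300
        g1 = rng.integers(0, 3, n)
        g2 = rng.integers(0, 3, n)
        y = 0.5 * g2 + 0.2 * g1 * g2 + rng.standard_normal(n)
        fit = fit_interaction(y, g1, g2)
        out = average_marginal_effects(fit, focal="g2", strata=g1)
        for _, row in out.iterrows():
            expect = fit.params["g2"] + fit.params["g1:g2"] * row["stratum"]
            assert row["ame"] == pytest.approx(expect, abs=1e-10)

    def test_strata_by_genotype_and_sex(self, rng):
        fit, g1, sex = self._binomial_fit(rng)
        labels = np.char.add(g1.astype(str), np.char.add("_", sex))
        out = average_marginal_effects(fit, focal="g2", strata=labels)
        assert set(out["stratum"]) == set(np.unique(labels))
        assert (out["se"] > 0).all()

    def test_delta_se_close_to_bootstrap(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.4, n)
        g2 = rng.binomial(2, 0.3, n)
        eta = -0.8 + 0.5 * g2 + 0.2 * g1 - 0.15 * g1 * g2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = fit_interaction(y, g1, g2, family="binomial")
        se = average_marginal_effects(fit, focal="g2")["se"].iloc[0]
        boots = []
        for _ in range(200):
            idx = rng.integers(0, n, n)
            try:
                bfit = fit_interaction(y[idx], g1[idx], g2[idx], family="binomial")
            except ValueError:
                continue
            boots.append(average_marginal_effects(bfit, focal="g2")["ame"].iloc[0])
        assert se == pytest.approx(np.std(boots, ddof=1), rel=0.15)


class TestOutlierFilter:
    def test_gross_outlier_removed_exactly(self, rng):
        n = 120
        X = rng.standard_normal((n, 2))
        y = X @ [1.0, -0.5] + rng.standard_normal(n)
        y[17] += 100.0
        keep, removed = studentized_outlier_filter(y, X)
        assert removed == 1
        assert 17 not in keep

    def test_idempotent_on_clean_data(self, rng):
        n = 500
        X = rng.standard_normal((n, 3))
        y = X @ [0.5, 0.2, -0.1] + rng.standard_normal(n)
        keep, removed = studentized_outlier_filter(y, X)
        keep2, removed2 = studentized_outlier_filter(y[keep], X[keep])
        assert removed2 == 0
        assert removed <= 2  # |t| > 4 on clean Gaussian data is ~never

    def test_heavy_removal_warns(self, rng):
        n = 60
        X = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        # an aggressive cutoff strips the distribution tails wholesale
        with pytest.warns(UserWarning, match="10%"):
            studentized_outlier_filter(y, X, cutoff=1.0)
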