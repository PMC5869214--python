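import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate
from scipy.special import expit

from andrias import glmm


def county_frame(prov, method, **cols):
    df = pd.DataFrame(
        {
            "county_id": np.arange(1, len(prov) + 1),
            "province": prov,
            "selection_method": method,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


def simulate_binomial(n_prov, per_prov, n, beta0, beta1, sig_p, sig_o, seed):
    rng = np.random.default_rng(seed)
    n_c = n_prov * per_prov
    prov = np.repeat(np.arange(1, n_prov + 1), per_prov)
    method = rng.integers(0, 2, n_c)
    eta = beta0 + beta1 * method + rng.normal(0, sig_p, n_prov)[prov - 1] \
        + rng.normal(0, sig_o, n_c)
    y = rng.binomial(n, expit(eta))
    return county_frame(prov, method, n_respondents=n, n_reported=y)


class TestTweedieDensity:
    def test_zero_mass_closed_form(self):
        # lambda = mu^(2-p) / (phi (2-p)) = 2 at (1, 1, 1.5)
        assert glmm.tweedie_log_density(0.0, 1.0, 1.0, 1.5) == pytest.approx(-2.0)

    @pytest.mark.parametrize(
        "mu,phi,p",
        [(1.0, 1.0, 1.5), (3.0, 2.0, 1.2), (0.5, 0.5, 1.8),
         (10.0, 3.0, 1.6), (2.0, 0.2, 1.35), (5.0, 5.0, 1.9)],
    )
    def test_density_normalises_to_one(self, mu, phi, p):
        p0 = np.exp(glmm.tweedie_log_density(0.0, mu, phi, p))
        f = lambda y: np.exp(glmm.tweedie_log_density(y, mu, phi, p))
        # split at 1 so quad resolves the y -> 0 power-law singularity
        head, _ = integrate.quad(f, 0.0, 1.0, limit=200)
        tail, _ = integrate.quad(f, 1.0, np.inf, limit=200)
        assert p0 + head + tail == pytest.approx(1.0, abs=1e-6)

    def test_matches_compound_poisson_gamma_simulation(self):
        mu, phi, p = 2.0, 1.5, 1.6
        rng = np.random.default_rng(10)
        lam = mu ** (2 - p) / (phi * (2 - p))
        alpha = (2 - p) / (p - 1)
        scale = phi * (p - 1) * mu ** (p - 1)
        counts = rng.poisson(lam, 400_000)
        draws = np.where(counts > 0, rng.gamma(np.maximum(counts, 1) * alpha, scale), 0.0)
        # point mass at zero
        p0_mc = (counts == 0).mean()
        p0 = np.exp(glmm.tweedie_log_density(0.0, mu, phi, p))
        assert p0_mc == pytest.approx(p0, abs=4 * np.sqrt(p0 * (1 - p0) / 4e5))
        # histogram of the continuous part vs integrated density
        edges = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        for lo, hi in zip(edges[:-1], edges[1:]):
            frac_mc = ((draws > lo) & (draws <= hi)).mean()
            frac, _ = integrate.quad(
                lambda y: np.exp(glmm.tweedie_log_density(y, mu, phi, p)), lo, hi
            )
            assert frac_mc == pytest.approx(frac, abs=4 * np.sqrt(frac * (1 - frac) / 4e5))

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="power"):
            glmm.tweedie_log_density(1.0, 1.0, 1.0, 2.5)
        with pytest.raises(ValueError, match="phi"):
            glmm.tweedie_log_density(1.0, 1.0, -1.0, 1.5)


class TestZeroVarianceLimits:
    """With no group-level variance the marginal models must collapse to
    their fixed-effects GLM counterparts."""

    def test_binomial_reduces_to_logistic_regression(self):
        df = simulate_binomial(6, 10, 30, -0.2, 1.0, 0.0, 0.0, seed=7)
        fit = glmm.fit_binomial_glmm(df, olre=False, fixed_sigma_province=0.0)
        X = sm.add_constant(df["selection_method"].to_numpy(float))
        resp = np.column_stack([df["n_reported"], df["n_respondents"] - df["n_reported"]])
        ref = sm.GLM(resp, X, family=sm.families.Binomial()).fit()
        assert fit.sigma_province == 0.0
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-4)
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-4)
        # a freely estimated province SD can only raise the likelihood
        free = glmm.fit_binomial_glmm(df, olre=False)
        assert free.log_likelihood >= ref.llf - 1e-6

    def test_poisson_reduces_to_poisson_glm(self):
        rng = np.random.default_rng(5)
        prov = np.repeat(np.arange(1, 7), 8)
        method = rng.integers(0, 2, 48)
        y = rng.poisson(np.exp(1.2 + 0.5 * method))
        df = county_frame(prov, method, min_years_ago=y.astype(float))
        fit = glmm.fit_count_glmm(df, family="poisson", fixed_sigma_province=0.0)
        X = sm.add_constant(method.astype(float))
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.sigma_province == 0.0
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_negbinomial_limit_equals_poisson(self):
        rng = np.random.default_rng(11)
        prov = np.repeat(np.arange(1, 7), 10)
        method = rng.integers(0, 2, 60)
        y = rng.poisson(np.exp(1.0 + 0.3 * method))
        df = county_frame(prov, method, min_years_ago=y.astype(float))
        f_pois = glmm.fit_count_glmm(df, family="poisson")
        f_nb = glmm.fit_count_glmm(df, family="negbinomial", fixed_theta=1e8)
        assert f_nb.log_likelihood == pytest.approx(f_pois.log_likelihood, abs=1e-4)

    def test_tweedie_reduces_to_fixed_effects_glm_coefficients(self):
        rng = np.random.default_rng(3)
        prov = np.repeat(np.arange(1, 7), 10)
        method = rng.integers(0, 2, 60)
        mu = np.exp(1.0 + 0.4 * method)
        p_true = 1.6
        lam = mu ** (2 - p_true) / (1.5 * (2 - p_true))
        counts = rng.poisson(lam)
        y = np.where(
            counts > 0,
            rng.gamma(np.maximum(counts, 1) * (2 - p_true) / (p_true - 1),
                      1.5 * (p_true - 1) * mu ** (p_true - 1)),
            0.0,
        )
        df = county_frame(prov, method, mean_years_ago=y)
        fit = glmm.fit_tweedie_glmm(
            df, power_grid=(p_true,), refine_power=False, n_starts=1,
            fixed_sigma_province=0.0,
        )
        X = sm.add_constant(method.astype(float))
        ref = sm.GLM(
            y, X, family=sm.families.Tweedie(var_power=p_true,
                                             link=sm.families.links.Log()),
        ).fit()
        assert fit.sigma_province == 0.0
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-3)
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-3)


class TestParameterRecovery:
    def test_binomial_method_effect_recovered(self):
        ests = []
        for s in range(20):
            df = simulate_binomial(25, 8, 30, -0.2, 1.0, 0.5, 0.0, seed=100 + s)
            fit = glmm.fit_binomial_glmm(df, olre=False, n_starts=1)
            ests.append(fit.beta1)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.1)

    def test_olre_variance_recovered(self):
        df = simulate_binomial(15, 10, 30, 0.0, 0.5, 0.4, 0.6, seed=42)
        fit = glmm.fit_binomial_glmm(df, olre=True)
        assert fit.sigma_olre == pytest.approx(0.6, abs=0.25)

    def test_negbinomial_theta_recovered(self):
        ests = []
        for s in range(6):
            rng = np.random.default_rng(900 + s)
            prov = np.repeat(np.arange(1, 16), 20)
            method = rng.integers(0, 2, 300)
            mu = np.exp(1.5 + 0.4 * method + rng.normal(0, 0.4, 15)[prov - 1])
            theta = 2.0
            y = rng.negative_binomial(theta, theta / (theta + mu))
            df = county_frame(prov, method, min_years_ago=y.astype(float))
            fit = glmm.fit_count_glmm(df, family="negbinomial", n_starts=1)
            ests.append(fit.dispersion)
        assert 1.5 <= np.mean(ests) <= 2.7

    def test_tweedie_effect_recovered(self):
        ests = []
        p_true, phi_true = 1.6, 2.0
        for s in range(8):
            rng = np.random.default_rng(50 + s)
            prov = np.repeat(np.arange(1, 11), 12)
            method = rng.integers(0, 2, 120)
            mu = np.exp(1.0 + 0.3 * method + rng.normal(0, 0.3, 10)[prov - 1])
            lam = mu ** (2 - p_true) / (phi_true * (2 - p_true))
            counts = rng.poisson(lam)
            y = np.where(
                counts > 0,
                rng.gamma(np.maximum(counts, 1) * (2 - p_true) / (p_true - 1),
                          phi_true * (p_true - 1) * mu ** (p_true - 1)),
                0.0,
            )
            df = county_frame(prov, method, mean_years_ago=y)
            fit = glmm.fit_tweedie_glmm(
                df, power_grid=(1.5, 1.6, 1.7), refine_power=False, n_starts=1
            )
            ests.append(fit.beta1)
        mean, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 0.3) <= max(3 * se, 0.1)


class TestOverdispersion:
    def test_pearson_ratio_arithmetic(self):
        assert glmm.pearson_dispersion([1, -1, 1, -1], 2) == 2.0
        with pytest.raises(ValueError):
            glmm.pearson_dispersion([1.0], 0)

    def test_well_specified_poisson_ratio_near_one(self):
        rng = np.random.default_rng(8)
        prov = np.repeat(np.arange(1, 11), 50)
        method = rng.integers(0, 2, 500)
        y = rng.poisson(np.exp(1.5 + 0.3 * method))
        df = county_frame(prov, method, min_years_ago=y.astype(float))
        fit = glmm.fit_count_glmm(df, family="poisson", n_starts=1)
        assert 0.8 <= glmm.overdispersion_ratio(fit, df) <= 1.2

    def test_poisson_fit_to_overdispersed_counts_inflates_ratio(self):
        rng = np.random.default_rng(9)
        prov = np.repeat(np.arange(1, 11), 30)
        method = rng.integers(0, 2, 300)
        mu = np.exp(1.5 + 0.2 * method)
        theta = 0.5
        y = rng.negative_binomial(theta, theta / (theta + mu))
        df = county_frame(prov, method, min_years_ago=y.astype(float))
        fit = glmm.fit_count_glmm(df, family="poisson", n_starts=1)
        assert glmm.overdispersion_ratio(fit, df) > 3.0

    def test_heavy_extra_binomial_noise_detected_and_absorbed(self):
        df = simulate_binomial(10, 10, 30, 0.0, 0.5, 0.3, 1.5, seed=13)
        plain = glmm.fit_binomial_glmm(df, olre=False)
        olre = glmm.fit_binomial_glmm(df, olre=True)
        ratio_plain = glmm.overdispersion_ratio(plain, df)
        ratio_olre = glmm.overdispersion_ratio(olre, df)
        assert ratio_plain >= 5.0
        assert ratio_olre < 1.5
        lrt = glmm.lr_test(plain, olre)
        assert lrt["p"] < 1e-6


class TestLikelihoodRatioTest:
    def test_identical_models_give_null_result(self, county_summaries):
        fit = glmm.fit_binomial_glmm(county_summaries, olre=False, n_starts=1)
        fit2 = glmm.ModelFit(**{**fit.__dict__, "n_parameters": fit.n_parameters + 1})
        res = glmm.lr_test(fit, fit2)
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_chi2_tail_worked_example(self):
        null = glmm.ModelFit(
            family="binomial", response="n_reported", include_method=False,
            beta0=0, beta1=None, sigma_province=0.1, sigma_olre=None,
            dispersion=None, tweedie_power=None, log_likelihood=-100.0,
            n_parameters=2, n_obs=50, converged=True, quadrature_points=15,
        )
        alt = glmm.ModelFit(**{**null.__dict__, "log_likelihood": -97.0,
                               "n_parameters": 3, "include_method": True, "beta1": 0.5})
        res = glmm.lr_test(null, alt)
        assert res["chi2"] == pytest.approx(6.0)
        assert res["p"] == pytest.approx(0.0143, abs=5e-4)

    def test_numerical_noise_clamped_with_warning(self):
        null = glmm.ModelFit(
            family="binomial", response="n_reported", include_method=False,
            beta0=0, beta1=None, sigma_province=0.1, sigma_olre=None,
            dispersion=None, tweedie_power=None, log_likelihood=-100.0,
            n_parameters=2, n_obs=50, converged=True, quadrature_points=15,
        )
        alt = glmm.ModelFit(**{**null.__dict__, "log_likelihood": -100.001,
                               "n_parameters": 3})
        with pytest.warns(RuntimeWarning, match="clamped"):
            res = glmm.lr_test(null, alt)
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_non_nested_rejected(self, county_summaries):
        fit = glmm.fit_binomial_glmm(county_summaries, olre=False, n_starts=1)
        with pytest.raises(ValueError, match="nested"):
            glmm.lr_test(fit, fit)

    def test_added_parameter_never_lowers_likelihood(self, county_summaries):
        plain = glmm.fit_binomial_glmm(county_summaries, olre=False)
        olre = glmm.fit_binomial_glmm(county_summaries, olre=True)
        assert olre.log_likelihood >= plain.log_likelihood - 1e-6
        null = glmm.fit_binomial_glmm(county_summaries, olre=True, include_method=False)
        assert olre.log_likelihood >= null.log_likelihood - 1e-6


class TestQuadratureStability:
    def test_estimates_stable_between_15_and_25_nodes(self, county_summaries):
        f15 = glmm.fit_binomial_glmm(county_summaries, olre=True, quadrature_points=15)
        f25 = glmm.fit_binomial_glmm(county_summaries, olre=True, quadrature_points=25)
        assert f15.beta1 == pytest.approx(f25.beta1, abs=1e-3)
        assert f15.sigma_province == pytest.approx(f25.sigma_province, abs=1e-3)
        assert f15.log_likelihood == pytest.approx(f25.log_likelihood, abs=1e-2)
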