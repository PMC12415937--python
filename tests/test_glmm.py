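import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from caaquant.families import squeeze_unit_interval, tweedie_logpdf, zib_logpdf
from caaquant.glmm import (GLMMOptions, ModelData, TweedieParams, ZIBetaParams,
                           estimated_marginal_means, fit_tweedie_glmm,
                           fit_zib_glmm, laplace_marginal_loglik, wald_test)
from caaquant.simulate import (DEFAULT_COVERAGE_PARAMS,
                               DEFAULT_INTRAMURAL_PARAMS,
                               simulate_tweedie_dataset, simulate_zib_dataset)

from _oracles import aghq_marginal_loglik


def _tiny_data(family, seed=7, n_mice=3, n_images=2, n_obs=4):
    rng = np.random.default_rng(seed)
    n = n_mice * n_images * n_obs
    mouse = np.repeat(np.arange(n_mice), n_images * n_obs)
    image = np.repeat(np.arange(n_mice * n_images), n_obs)
    group = (mouse >= (n_mice + 1) // 2).astype(int)
    if family == "zibeta":
        y = rng.uniform(0.05, 0.7, n)
        y[rng.choice(n, max(n // 6, 1), replace=False)] = 0.0
    else:
        y = rng.gamma(2.0, 3.0, n)
        y[rng.choice(n, max(n // 6, 1), replace=False)] = 0.0
    return ModelData(y=y, group=group, mouse=mouse, image=image)


class TestWaldTest:
    @pytest.mark.parametrize("est,se,z_expected", [
        (-0.242, 0.234, -1.033),   # arteriole coverage group effect
        (-0.557, 0.243, -2.295),   # intramural aggregate size group effect
        (-0.477, 0.383, -1.246),   # extramural aggregate size group effect
    ])
    def test_reported_z_reproduced_from_estimate_and_se(self, est, se, z_expected):
        z, p = wald_test(est, se)
        assert z == pytest.approx(z_expected, abs=0.01)
        assert 0.0 <= p <= 1.0

    def test_null_estimate(self):
        z, p = wald_test(0.0, 1.7)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestLaplaceMarginal:
    def test_zero_sigmas_give_exact_iid_loglik_zibeta(self):
        data = _tiny_data("zibeta")
        params = ZIBetaParams(beta0=-1.0, beta1=-0.3, phi=5.0, gamma0=-1.5)
        ll = laplace_marginal_loglik(data, params, "zibeta")
        y = data.y.copy()
        pos = y > 0
        y[pos] = squeeze_unit_interval(y[pos], n=int(pos.sum()))
        eta = params.beta0 + params.beta1 * data.group
        direct = float(np.sum(zib_logpdf(y, expit(eta), params.phi,
                                         expit(params.gamma0))))
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_zero_sigmas_give_exact_iid_loglik_tweedie(self):
        data = _tiny_data("tweedie")
        params = TweedieParams(beta0=1.5, beta1=-0.4, phi=1.5, p=1.6)
        ll = laplace_marginal_loglik(data, params, "tweedie")
        mu = np.exp(params.beta0 + params.beta1 * data.group)
        direct = float(np.sum(tweedie_logpdf(data.y, mu, params.phi, params.p)))
        assert ll == pytest.approx(direct, rel=1e-10)

    @pytest.mark.parametrize("family,params", [
        ("zibeta", ZIBetaParams(beta0=-1.0, beta1=-0.3, phi=10.0, gamma0=-1.5,
                                sigma_mouse=0.1, sigma_image=0.1)),
        ("tweedie", TweedieParams(beta0=1.5, beta1=-0.4, phi=1.5, p=1.6,
                                  sigma_mouse=0.15, sigma_image=0.12)),
    ])
    def test_agrees_with_adaptive_quadrature_on_tiny_fixtures(self, family, params):
        data = _tiny_data(family, n_mice=2, n_images=2, n_obs=3)
        lap = laplace_marginal_loglik(data, params, family)
        ora = aghq_marginal_loglik(data, params, family)
        assert lap == pytest.approx(ora, rel=1e-3)

    def test_invariant_to_relabelling_of_clusters(self, rng):
        data = _tiny_data("tweedie", n_mice=4, n_images=2, n_obs=3)
        params = TweedieParams(beta0=1.5, beta1=-0.4, phi=1.5, p=1.6,
                               sigma_mouse=0.3, sigma_image=0.2)
        base = laplace_marginal_loglik(data, params, "tweedie")
        perm = rng.permutation(data.n_obs)
        shuffled = ModelData(y=data.y[perm], group=data.group[perm],
                             mouse=data.mouse[perm] + 100,
                             image=data.image[perm] + 500)
        assert laplace_marginal_loglik(shuffled, params, "tweedie") == \
            pytest.approx(base, rel=1e-9)

    def test_duplicating_observations_halves_squared_se(self):
        # at sigma = 0 the information is additive, so SEs shrink by sqrt(2)
        frame = simulate_zib_dataset(
            ZIBetaParams(beta0=-1.5, beta1=-0.3, phi=4.0, gamma0=-1.0),
            mice_per_group=3, images_per_mouse=2, units_per_image=10,
            rng=np.random.default_rng(4))
        opts = GLMMOptions(n_restarts=1, fix_sigmas=True)
        data1 = ModelData.from_frame(frame, "value")
        doubled = pd.concat([frame, frame], ignore_index=True)
        data2 = ModelData.from_frame(doubled, "value")
        se1 = fit_zib_glmm(data1, opts).fixed_effects.set_index("term").loc[
            "mu_group", "se"]
        se2 = fit_zib_glmm(data2, opts).fixed_effects.set_index("term").loc[
            "mu_group", "se"]
        assert se2 * np.sqrt(2.0) == pytest.approx(se1, rel=0.02)


class TestFitting:
    def test_all_zero_coverage_is_degenerate(self):
        data = ModelData(y=np.zeros(24),
                         group=np.repeat([0, 1], 12),
                         mouse=np.repeat([0, 1, 2, 3], 6),
                         image=np.repeat(np.arange(8), 3))
        with pytest.raises(ValueError, match="unidentified"):
            fit_zib_glmm(data)

    def test_coverage_outside_unit_interval_rejected(self):
        data = _tiny_data("zibeta")
        data.y[0] = 1.4
        with pytest.raises(ValueError):
            fit_zib_glmm(data)

    def test_negative_sizes_rejected(self):
        data = _tiny_data("tweedie")
        data.y[0] = -2.0
        with pytest.raises(ValueError):
            fit_tweedie_glmm(data)

    def test_sigma_zero_data_matches_fixed_effects_only_path(self):
        params = TweedieParams(beta0=2.0, beta1=-0.5, phi=1.5, p=1.6)
        frame = simulate_tweedie_dataset(params, 3, 3, 10,
                                         rng=np.random.default_rng(9))
        data = ModelData.from_frame(frame, "value")
        free = fit_tweedie_glmm(data, GLMMOptions(n_restarts=1))
        fixed = fit_tweedie_glmm(data, GLMMOptions(n_restarts=1,
                                                   fix_sigmas=True))
        b_free = free.fixed_effects.set_index("term")["estimate"]
        b_fixed = fixed.fixed_effects.set_index("term")["estimate"]
        assert b_free["group"] == pytest.approx(b_fixed["group"], abs=0.02)

    def test_z_equals_estimate_over_se(self):
        frame = simulate_tweedie_dataset(DEFAULT_INTRAMURAL_PARAMS, 3, 3, 8,
                                         rng=np.random.default_rng(2))
        fit = fit_tweedie_glmm(ModelData.from_frame(frame, "value"),
                               GLMMOptions(n_restarts=1))
        fe = fit.fixed_effects
        np.testing.assert_allclose(fe["z"], fe["estimate"] / fe["se"],
                                   rtol=1e-12)

    def test_recovers_effect_direction_at_study_scale(self):
        frame = simulate_zib_dataset(DEFAULT_COVERAGE_PARAMS, 5, 5, 10,
                                     rng=np.random.default_rng(1))
        fit = fit_zib_glmm(ModelData.from_frame(frame, "value"),
                           GLMMOptions(n_restarts=1))
        assert fit.converged
        est = fit.fixed_effects.set_index("term").loc["mu_group", "estimate"]
        assert abs(est - DEFAULT_COVERAGE_PARAMS.beta1) < 0.5

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError, match="nest"):
            ModelData(y=np.ones(4) * 0.2, group=[0, 0, 1, 1],
                      mouse=[0, 0, 1, 1], image=[0, 0, 0, 1])


class TestMarginalMeans:
    def _fit_on(self, frame, family, **opt):
        data = ModelData.from_frame(frame, "value")
        fun = fit_zib_glmm if family == "zibeta" else fit_tweedie_glmm
        return fun(data, GLMMOptions(n_restarts=1, **opt))

    def test_tweedie_means_exponentiate_linear_predictor(self):
        params = TweedieParams(beta0=2.0, beta1=-0.5, phi=1.5, p=1.6)
        frame = simulate_tweedie_dataset(params, 4, 3, 12,
                                         rng=np.random.default_rng(3))
        fit = self._fit_on(frame, "tweedie")
        emm = estimated_marginal_means(fit).set_index("group")
        b = fit.fixed_effects.set_index("term")["estimate"]
        assert emm.loc["control", "mean"] == pytest.approx(np.exp(b["(Intercept)"]))
        assert emm.loc["clu", "mean"] == pytest.approx(
            np.exp(b["(Intercept)"] + b["group"]))
        assert (emm["ci_low"] <= emm["mean"]).all()
        assert (emm["mean"] <= emm["ci_high"]).all()

    def test_zib_overall_mean_combines_zero_and_beta_parts(self):
        params = ZIBetaParams(beta0=-1.0, beta1=-0.3, phi=6.0, gamma0=-0.8)
        frame = simulate_zib_dataset(params, 4, 3, 12,
                                     rng=np.random.default_rng(8))
        fit = self._fit_on(frame, "zibeta")
        emm = estimated_marginal_means(fit).set_index("group")
        th = fit.fixed_effects.set_index("term")["estimate"]
        mu0 = expit(th["mu_(Intercept)"])
        pi0 = expit(th["zi_(Intercept)"])
        assert emm.loc["control", "mean"] == pytest.approx((1 - pi0) * mu0)

    def test_conditional_kind_reports_beta_mean(self):
        params = ZIBetaParams(beta0=-1.0, beta1=0.0, phi=6.0, gamma0=-0.8)
        frame = simulate_zib_dataset(params, 4, 3, 12,
                                     rng=np.random.default_rng(8))
        fit = self._fit_on(frame, "zibeta")
        emm = estimated_marginal_means(fit, kind="conditional").set_index("group")
        th = fit.fixed_effects.set_index("term")["estimate"]
        assert emm.loc["control", "mean"] == pytest.approx(
            expit(th["mu_(Intercept)"]))

    def test_delta_ci_agrees_with_monte_carlo_propagation(self):
        # sigma = 0 fixture: push 2000 normal draws of the parameters through
        # the mean transform and compare the percentile interval
        params = TweedieParams(beta0=2.0, beta1=-0.5, phi=1.5, p=1.6)
        frame = simulate_tweedie_dataset(params, 4, 4, 15,
                                         rng=np.random.default_rng(12))
        fit = self._fit_on(frame, "tweedie", fix_sigmas=True)
        emm = estimated_marginal_means(fit).set_index("group")
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(fit.theta, fit.cov, size=2000)
        for g, label in enumerate(("control", "clu")):
            means = np.exp(draws[:, 0] + draws[:, 1] * g)
            lo, hi = np.quantile(means, [0.025, 0.975])
            assert emm.loc[label, "ci_low"] == pytest.approx(lo, rel=0.10)
            assert emm.loc[label, "ci_high"] == pytest.approx(hi, rel=0.10)

    def test_non_converged_fit_rejected(self):
        params = TweedieParams(beta0=2.0, beta1=-0.5, phi=1.5, p=1.6)
        frame = simulate_tweedie_dataset(params, 3, 2, 8,
                                         rng=np.random.default_rng(3))
        fit = self._fit_on(frame, "tweedie")
        fit.converged = False
        with pytest.raises(ValueError):
            estimated_marginal_means(fit)
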