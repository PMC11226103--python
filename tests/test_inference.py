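"""Sampler correctness: conjugacy algebra, determinism, a griddled-posterior
oracle for the precision marginal, Laplace stationarity, summary oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import cropclim as cc
from cropclim.inference import McmcConfig, gibbs_update_precision, summarize


class TestGibbsPrecision:
    PRIOR = cc.PriorConfig(hyper_shape=1.0, hyper_rate=0.00005)

    def test_conjugacy_algebra_iid(self):
        # sum(gamma^2)=2, n=4 -> Gamma(shape 1+2, rate 0.00005+1): the draw
        # must reproduce an independent generator's draw at those parameters
        effects = np.array([1.0, -1.0, 0.0, 0.0])
        draw = gibbs_update_precision(
            effects, "iid", self.PRIOR, np.random.default_rng(5)
        )
        expected = np.random.default_rng(5).gamma(3.0, 1.0 / 1.00005)
        assert draw == expected

    def test_zero_effects_posterior_is_prior_rate(self):
        draw = gibbs_update_precision(
            np.zeros(6), "iid", self.PRIOR, np.random.default_rng(9)
        )
        expected = np.random.default_rng(9).gamma(
            1.0 + 3.0, 1.0 / self.PRIOR.hyper_rate
        )
        assert draw == expected

    def test_rw1_uses_successive_differences(self):
        delta = np.array([0.0, 1.0, -1.0])
        q = 1.0 + 4.0  # (1-0)^2 + (-1-1)^2
        draw = gibbs_update_precision(
            delta, "rw1", self.PRIOR, np.random.default_rng(2)
        )
        expected = np.random.default_rng(2).gamma(
            1.0 + 1.0, 1.0 / (0.00005 + q / 2.0)
        )
        assert draw == expected

    def test_rw1_too_short_rejected(self):
        with pytest.raises(ValueError):
            gibbs_update_precision(
                np.array([1.0]), "rw1", self.PRIOR, np.random.default_rng(0)
            )

    def test_distributional_oracle_ks(self):
        rng = np.random.default_rng(77)
        effects = rng.normal(0.0, 0.5, size=8)
        draws = np.array(
            [
                gibbs_update_precision(effects, "iid", self.PRIOR, rng)
                for _ in range(10_000)
            ]
        )
        shape = 1.0 + 4.0
        rate = 0.00005 + 0.5 * float(effects @ effects)
        ks = stats.kstest(draws, stats.gamma(a=shape, scale=1.0 / rate).cdf)
        assert ks.statistic < 1.628 / np.sqrt(10_000)  # 1% critical value


class TestSamplePosterior:
    def test_same_seed_identical_draws(self, small_design):
        cfg = McmcConfig(n_chains=2, n_warmup=50, n_samples=50, seed=3)
        a = cc.sample_posterior(small_design, config=cfg)
        b = cc.sample_posterior(small_design, config=cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.tau_delta, b.tau_delta)

    def test_draw_invariants(self, small_design):
        cfg = McmcConfig(n_chains=2, n_warmup=200, n_samples=200, seed=8)
        draws = cc.sample_posterior(small_design, config=cfg)
        assert (draws.tau_gamma > 0).all() and (draws.tau_delta > 0).all()
        assert np.abs(draws.delta.sum(axis=2)).max() < 1e-8

    def test_recovery_and_convergence_smoke(self, small_truth, small_design):
        cfg = McmcConfig(n_chains=4, n_warmup=500, n_samples=500, seed=4)
        draws = cc.sample_posterior(small_design, config=cfg)
        s = summarize(draws).set_index("parameter")
        assert s.loc["alpha", "rhat"] < 1.05
        assert s.loc["beta", "rhat"] < 1.05
        beta_true = small_truth.config.beta_true
        lo, hi = s.loc["beta", "q2.5"], s.loc["beta", "q97.5"]
        width = hi - lo
        assert lo - width <= beta_true <= hi + width  # loose single-run check

    def test_empty_data_rejected(self):
        data = cc.ModelData(
            y=[], offset_eps=[], x=[], muni_index=[], year_index=[], N=0, T=0
        )
        with pytest.raises(ValueError):
            cc.sample_posterior(data)

    def test_tau_gamma_marginal_matches_griddled_posterior(self):
        """Kolmogorov distance between sampled tau_gamma and an
        independently integrated marginal posterior on a tiny instance."""
        y = np.array([55, 70, 48])
        eps = np.array([50, 80, 40])
        data = cc.ModelData(
            y=y, offset_eps=eps, x=np.zeros(3),
            muni_index=[0, 1, 2], year_index=[0, 0, 0], N=3, T=1,
        )
        prior = cc.PriorConfig(
            fixed_effect_precision=1.0, hyper_shape=2.0, hyper_rate=1.0
        )
        cfg = McmcConfig(n_chains=2, n_warmup=2000, n_samples=25_000, seed=6)
        draws = cc.sample_posterior(data, prior, cfg).tau_gamma.reshape(-1)

        # oracle: p(tau|y) ∝ Gamma(tau;a,b) ∫ N(alpha) Π_i I_i(alpha,tau) dα
        # with I_i a 1-d quadrature over the municipality effect
        alphas = np.linspace(-1.5, 1.5, 401)
        taus = np.geomspace(1e-2, 60.0, 500)
        log_post = np.empty_like(taus)
        for j, tau in enumerate(taus):
            sd = 1.0 / np.sqrt(tau)
            g = np.linspace(-7 * sd, 7 * sd, 401)
            # I[i, k] = ∫ Pois(y_i | eps_i e^{alpha_k + g}) N(g|0,1/tau) dg
            loglam = np.log(eps)[:, None, None] + alphas[None, :, None] + g[None, None, :]
            ll = (
                y[:, None, None] * loglam
                - np.exp(loglam)
                + stats.norm.logpdf(g, scale=sd)[None, None, :]
            )
            m = ll.max(axis=2, keepdims=True)
            I = np.trapezoid(np.exp(ll - m), g, axis=2) * np.exp(m[:, :, 0])
            integrand = stats.norm.pdf(alphas) * np.prod(I, axis=0)
            log_post[j] = stats.gamma.logpdf(tau, a=2.0, scale=1.0) + np.log(
                np.trapezoid(integrand, alphas)
            )
        dens = np.exp(log_post - log_post.max())
        cdf = integrate.cumulative_trapezoid(dens, taus, initial=0.0)
        cdf /= cdf[-1]

        xs = np.sort(draws)
        ecdf = np.arange(1, len(xs) + 1) / len(xs)
        oracle_cdf = np.interp(xs, taus, cdf)
        ks = np.abs(ecdf - oracle_cdf).max()
        assert ks < 0.03


class TestLaplace:
    def test_prior_mode_without_observations(self):
        data = cc.ModelData(
            y=[], offset_eps=[], x=[], muni_index=[], year_index=[], N=2, T=1
        )
        fit = cc.laplace_fit(data, precisions=(1.0, 1.0))
        assert fit.alpha == pytest.approx(0.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.gamma, 0.0)

    def test_intercept_only_stationarity_equation(self):
        # single observation, no random effects: the mode of alpha solves
        # y - eps*e^alpha - prec*alpha = 0; verify by substitution
        data = cc.ModelData(
            y=[54], offset_eps=[20], x=[0.0], muni_index=[0], year_index=[0],
            N=1, T=1,
        )
        prior = cc.PriorConfig(fixed_effect_precision=2.0)
        # neutralize the municipality effect by a huge precision
        fit = cc.laplace_fit(data, prior, precisions=(1e12, 1.0))
        resid = 54 - 20 * np.exp(fit.alpha) - 2.0 * fit.alpha
        assert abs(resid) < 1e-6

    def test_cross_engine_agreement(self, small_design):
        fit = cc.laplace_fit(small_design)
        cfg = McmcConfig(n_chains=4, n_warmup=500, n_samples=500, seed=11)
        draws = cc.sample_posterior(small_design, config=cfg)
        beta_mcmc = draws.beta.mean()
        assert abs(fit.beta - beta_mcmc) < 0.5 * fit.sd_beta


class TestSummarize:
    def _draws(self, alpha, beta=None):
        alpha = np.asarray(alpha, dtype=float)
        beta = alpha if beta is None else np.asarray(beta, dtype=float)
        c, s = alpha.shape
        return cc.PosteriorDraws(
            alpha=alpha,
            beta=beta,
            gamma=np.zeros((c, s, 1)),
            delta=np.zeros((c, s, 1)),
            tau_gamma=np.ones((c, s)),
            tau_delta=np.ones((c, s)),
        )

    def test_degenerate_constant_chains(self):
        s = summarize(self._draws(np.full((2, 10), 3.25))).set_index("parameter")
        assert s.loc["alpha", "mean"] == 3.25
        assert s.loc["alpha", "sd"] == 0.0

    def test_pooled_quantiles_permutation_invariant(self, rng):
        vals = np.arange(1.0, 10001.0)
        a = self._draws(vals.reshape(2, 5000))
        b = self._draws(rng.permutation(vals).reshape(2, 5000))
        sa = summarize(a).set_index("parameter")
        sb = summarize(b).set_index("parameter")
        assert sa.loc["alpha", "q2.5"] == sb.loc["alpha", "q2.5"]
        assert sa.loc["alpha", "q97.5"] == sb.loc["alpha", "q97.5"]

    def test_quantiles_match_full_sort_oracle(self, rng):
        vals = rng.normal(0, 1, size=1000)
        s = summarize(self._draws(vals.reshape(2, 500))).set_index("parameter")
        # independent full-sort linear-interpolation quantile
        xs = np.sort(vals)
        for q, col in ((0.025, "q2.5"), (0.975, "q97.5")):
            pos = q * (len(xs) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            oracle = xs[lo] + (pos - lo) * (xs[hi] - xs[lo])
            assert s.loc["alpha", col] == pytest.approx(oracle, rel=1e-12)

    def test_single_chain_rhat_unavailable(self, rng):
        s = summarize(
            self._draws(rng.normal(size=(1, 100)))
        ).set_index("parameter")
        assert np.isnan(s.loc["alpha", "rhat"])
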