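"""The collapsed posterior: transforms, density value, analytic gradient.

These are the load-bearing correctness checks for the sampler and the
evidence estimator: the collapsed density must equal the brute-force
marginal density (per-PI effects integrated analytically), its gradient
must match finite differences, and every change-of-variables Jacobian
must be mass-preserving (checked by integrating the LKJ-Cholesky prior
to unit mass through the unconstrained parameterization).
"""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import small_observations
from pitrend._transforms import CorrCholTransform
from pitrend.collapsed import CollapsedPosterior
from pitrend.model import (PriorConfig, build_design_matrix,
                           half_normal_logpdf, half_t_logpdf,
                           lkj_cholesky_logpdf)


class TestCorrCholTransform:
    @pytest.mark.parametrize("dim", [2, 3, 5])
    def test_round_trip(self, dim):
        rng = np.random.default_rng(dim)
        transform = CorrCholTransform(dim)
        y = rng.normal(0, 1, transform.n_params)
        L, _, _ = transform.forward(y)
        np.testing.assert_allclose((L ** 2).sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(transform.inverse(L), y, atol=1e-8)

    def test_vjp_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        transform = CorrCholTransform(4)
        y = rng.normal(0, 0.8, transform.n_params)
        weights = rng.normal(size=(4, 4))

        def objective(yy):
            L, jac, _ = transform.forward(yy)
            return float(np.sum(np.tril(weights) * L)) + jac

        L, _, caches = transform.forward(y)
        grad = transform.vjp(L, caches, np.tril(weights),
                             include_jacobian=True)
        h = 1e-6
        for k in range(transform.n_params):
            up, down = y.copy(), y.copy()
            up[k] += h
            down[k] -= h
            fd = (objective(up) - objective(down)) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_lkj_prior_mass_is_one_in_d3(self):
        """Monte-Carlo integral of the LKJ-Cholesky density over the
        unconstrained coordinates must be 1 (Jacobian correctness)."""
        transform = CorrCholTransform(3)
        rng = np.random.default_rng(0)
        # importance sample from a wide normal over y
        scale = 2.0
        y = rng.normal(0, scale, size=(200_000, transform.n_params))
        log_q = stats.norm.logpdf(y, scale=scale).sum(axis=1)
        values = np.empty(len(y))
        for i, yi in enumerate(y):
            L, jac, _ = transform.forward(yi)
            values[i] = lkj_cholesky_logpdf(L, 4.0) + jac - log_q[i]
        mass = np.exp(values - values.max()).mean() * np.exp(values.max())
        assert mass == pytest.approx(1.0, rel=0.02)


class TestCollapsedDensity:
    @pytest.fixture(scope="class")
    @staticmethod
    def posterior():
        obs, spec = small_observations(seed=0)
        return CollapsedPosterior(obs, spec, PriorConfig()), obs, spec

    def test_value_matches_naive_marginal(self, posterior):
        post, obs, spec = posterior
        pc = post.priors
        corr = post.corr
        rng = np.random.default_rng(10)
        for _ in range(4):
            theta = rng.normal(0, 0.7, post.n_params)
            p = post.p
            mu, u, y, v = theta[:p], theta[p:2 * p], theta[2 * p:-1], theta[-1]
            zeta, sigma = np.exp(u), math.exp(v)
            L, jac, _ = corr.forward(y)
            Sigma = (np.diag(zeta) @ L) @ (np.diag(zeta) @ L).T
            expected = 0.0
            groups = {}
            for o in obs:
                groups.setdefault(o.pi_id, []).append(o)
            for pid in sorted(groups):
                X = build_design_matrix(groups[pid], spec)
                d = np.array([o.d for o in groups[pid]])
                C = X @ Sigma @ X.T + sigma ** 2 * np.eye(len(d))
                expected += stats.multivariate_normal.logpdf(d, X @ mu, C)
            expected += float(np.sum(stats.norm.logpdf(
                mu, scale=pc.mu_scales(p))))
            expected += float(np.sum(half_t_logpdf(zeta, pc.zeta_df,
                                                   pc.zeta_scale))) + u.sum()
            expected += half_normal_logpdf(sigma, pc.sigma_scale) + v
            expected += lkj_cholesky_logpdf(L, pc.lkj_shape) + jac
            assert post.logp(theta) == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self, posterior):
        post, _, _ = posterior
        rng = np.random.default_rng(11)
        theta = rng.normal(0, 0.5, post.n_params)
        lp, grad = post.logp_grad(theta)
        assert np.isfinite(lp)
        h = 1e-5
        for k in range(post.n_params):
            up, down = theta.copy(), theta.copy()
            up[k] += h
            down[k] -= h
            fd = (post.logp(up) - post.logp(down)) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_nonfinite_input_rejected_gracefully(self, posterior):
        post, _, _ = posterior
        theta = np.zeros(post.n_params)
        theta[0] = np.inf
        assert post.logp(theta) == -np.inf

    def test_pack_unpack_round_trip(self, posterior):
        post, _, _ = posterior
        rng = np.random.default_rng(12)
        theta = rng.normal(0, 0.5, post.n_params)
        h = post.unpack(theta)
        np.testing.assert_allclose(post.pack(h), theta, atol=1e-8)

    def test_shrinking_zeta_approaches_pooled_regression(self):
        """With zeta -> 0 the hierarchy degenerates to one shared beta:
        the collapsed likelihood tends to the pooled fixed-effects
        Gaussian density."""
        obs, spec = small_observations(seed=4, n_pis=4,
                                       predictors=("age",), quadratic=False)
        post = CollapsedPosterior(obs, spec, PriorConfig())
        p = spec.dim
        rng = np.random.default_rng(5)
        mu = rng.normal(0, 0.5, p)
        sigma = 1.5
        X = build_design_matrix(obs, spec)
        d = np.array([o.d for o in obs])
        pooled = float(np.sum(stats.norm.logpdf(d, X @ mu, sigma)))
        for log_zeta, tol in ((-10.0, 5e-3), (-14.0, 1e-6)):
            theta = np.concatenate([
                mu, np.full(p, log_zeta),
                np.zeros(post.n_params - 2 * p - 1), [math.log(sigma)]])
            # subtract every prior/Jacobian term to isolate the likelihood
            prior_only = CollapsedPosterior(
                [type(obs[0])(o.pi_id, o.duration_day0, o.duration_next, 0.0,
                              o.covariates) for o in obs], spec,
                PriorConfig())
            delta = post.logp(theta) - prior_only.logp(theta)
            X0 = build_design_matrix(obs, spec)
            pooled_delta = pooled - float(
                np.sum(stats.norm.logpdf(np.zeros_like(d), X0 @ mu, sigma)))
            assert delta == pytest.approx(pooled_delta, abs=tol)

    def test_conditional_effects_match_direct_gls(self, posterior):
        """Per-PI conditional moments equal the textbook Gaussian
        posterior for beta_i given mu, Sigma, sigma."""
        post, obs, spec = posterior
        rng = np.random.default_rng(13)
        theta = rng.normal(0, 0.4, post.n_params)
        h = post.unpack(theta)
        pi_ids, means, covs = post.conditional_effect_moments(h)
        Sigma = h.covariance
        groups = {}
        for o in obs:
            groups.setdefault(o.pi_id, []).append(o)
        for g, pid in enumerate(pi_ids):
            X = build_design_matrix(groups[pid], spec)
            d = np.array([o.d for o in groups[pid]])
            prec = np.linalg.inv(Sigma) + X.T @ X / h.sigma ** 2
            cov = np.linalg.inv(prec)
            mean = cov @ (np.linalg.inv(Sigma) @ h.mu
                          + X.T @ d / h.sigma ** 2)
            np.testing.assert_allclose(means[g], mean, atol=1e-10)
            np.testing.assert_allclose(covs[g], cov, atol=1e-10)
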