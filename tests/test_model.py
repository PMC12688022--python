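"""Model structure: design rows, covariance assembly, densities."""

import math

import numpy as np
import pytest
from scipy import stats

from pitrend.model import (Hyperparameters, ModelSpec, PerPIEffects,
                           PriorConfig, ScoreChangeObservation,
                           assemble_covariance_chol, build_design_row,
                           half_normal_logpdf, lkj_cholesky_logpdf,
                           log_likelihood, log_prior)


def obs(pi_id="a", t=0.0, s=7.0, d=0.0, **cov):
    return ScoreChangeObservation(pi_id=pi_id, duration_day0=t,
                                  duration_next=s, d=d, covariates=cov)


class TestDesignRow:
    def test_base_plus_quadratic(self):
        spec = ModelSpec(include_quadratic_duration=True)
        assert build_design_row(obs(s=7), spec).tolist() == [1, 7, 49]

    def test_zero_duration(self):
        spec = ModelSpec(predictors=("age",),
                         include_quadratic_duration=True)
        row = build_design_row(obs(s=0, age=80.0), spec)
        assert row.tolist() == [1, 0, 0, 80.0]

    def test_best_model_row_order(self):
        spec = ModelSpec.published_best_structure()
        assert spec.dim == 7
        row = build_design_row(obs(t=10.0, s=7.0, baseline_score=15.0,
                                   age=80.0), spec)
        assert row.tolist() == [1, 7, 49, 10, 100, 15, 80]

    def test_missing_covariate_named(self):
        spec = ModelSpec(predictors=("age",))
        with pytest.raises(KeyError, match="age"):
            build_design_row(obs(), spec)

    def test_duplicate_predictor_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=("age", "age"))


class TestCovarianceAssembly:
    def test_identity(self):
        out = assemble_covariance_chol(np.ones(2), np.eye(2))
        np.testing.assert_allclose(out, np.eye(2))

    def test_scaling(self):
        out = assemble_covariance_chol(np.array([2.0, 3.0]), np.eye(2))
        np.testing.assert_allclose(out, np.diag([2.0, 3.0]))

    def test_negative_zeta_rejected(self):
        with pytest.raises(ValueError):
            assemble_covariance_chol(np.array([-1.0, 1.0]), np.eye(2))

    @pytest.mark.parametrize("seed", range(3))
    def test_random_inputs_give_psd_covariance(self, seed):
        """Sigma = B B' must be symmetric PSD with diagonal zeta^2."""
        rng = np.random.default_rng(seed)
        p = 4
        zeta = rng.uniform(0.1, 2.0, p)
        raw = rng.normal(size=(p, p))
        L = np.tril(raw)
        L /= np.linalg.norm(L, axis=1, keepdims=True)
        B = assemble_covariance_chol(zeta, L)
        Sigma = B @ B.T
        np.testing.assert_allclose(Sigma, Sigma.T)
        assert np.all(np.linalg.eigvalsh(Sigma) > -1e-12)
        np.testing.assert_allclose(np.diag(Sigma), zeta ** 2)


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        spec = ModelSpec()
        effects = PerPIEffects({"a": np.array([2.0, -0.5])})
        one = [obs(d=2.0 - 0.5 * 7.0)]
        value = log_likelihood(one, spec, effects, sigma=1.0)
        assert value == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_sigma_doubling_identity(self):
        spec = ModelSpec()
        effects = PerPIEffects({"a": np.array([2.0, -0.5])})
        one = [obs(d=2.0 - 0.5 * 7.0)]
        delta = (log_likelihood(one, spec, effects, 2.0)
                 - log_likelihood(one, spec, effects, 1.0))
        assert delta == pytest.approx(-math.log(2.0))

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        spec = ModelSpec(predictors=("age",))
        effects = PerPIEffects({f"p{k}": rng.normal(size=3)
                                for k in range(3)})
        observations = [obs(pi_id=f"p{k % 3}", s=float(rng.integers(1, 20)),
                            d=float(rng.normal()), age=float(rng.normal(80, 5)))
                        for k in range(9)]
        sigma = 1.7
        expected = 0.0
        for o in observations:
            x = build_design_row(o, spec)
            expected += stats.norm.logpdf(o.d, x @ effects.beta[o.pi_id],
                                          sigma)
        value = log_likelihood(observations, spec, effects, sigma)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_pi_relabelling_invariance(self):
        rng = np.random.default_rng(2)
        spec = ModelSpec()
        beta = {k: rng.normal(size=2) for k in ("a", "b")}
        observations = [obs(pi_id=k, s=float(s), d=float(rng.normal()))
                        for k in ("a", "b") for s in (7, 14)]
        base = log_likelihood(observations, spec, PerPIEffects(beta), 1.0)
        relabel = {"a": "b", "b": "a"}
        swapped = [ScoreChangeObservation(relabel[o.pi_id], o.duration_day0,
                                          o.duration_next, o.d, o.covariates)
                   for o in observations]
        swapped_beta = {relabel[k]: v for k, v in beta.items()}
        assert log_likelihood(swapped, spec, PerPIEffects(swapped_beta),
                              1.0) == pytest.approx(base)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            log_likelihood([], ModelSpec(), PerPIEffects({}), 0.0)


class TestLogPrior:
    def test_lkj_identity_dimension2(self):
        """In d=2 the LKJ(eta) density over the correlation r is
        (1-r^2)^(eta-1) / (2^(2 eta - 1) B(eta, eta)); at r=0 only the
        normalizer remains."""
        eta = 4.0
        expected = -((2 * eta - 1) * math.log(2.0)
                     + math.lgamma(eta) * 2 - math.lgamma(2 * eta))
        assert lkj_cholesky_logpdf(np.eye(2), eta) == pytest.approx(expected)

    def test_lkj_normalization_by_quadrature_d2(self):
        from scipy.integrate import quad

        def density(r):
            L = np.array([[1.0, 0.0], [r, math.sqrt(1 - r * r)]])
            # d Omega_21 / d L_21 = 1, so the L density is the r density
            return math.exp(lkj_cholesky_logpdf(L, 4.0))

        mass, _ = quad(density, -1, 1)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_sigma_prior_at_zero(self):
        value = half_normal_logpdf(0.0, 100.0)
        assert value == pytest.approx(
            math.log(2.0) + stats.norm.logpdf(0.0, scale=100.0))

    def test_monotone_decrease_away_from_mu(self):
        p = 3
        h = Hyperparameters(mu=np.zeros(p), zeta=np.ones(p),
                            omega_chol=np.eye(p), sigma=1.0)
        pc = PriorConfig()
        direction = np.array([1.0, 0.0, 0.0])  # a Sigma eigenvector
        values = [log_prior(h, PerPIEffects({"a": t * direction}), pc)
                  for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_degenerate_covariance_rejected(self):
        h = Hyperparameters(mu=np.zeros(2), zeta=np.array([0.0, 1.0]),
                            omega_chol=np.eye(2), sigma=1.0)
        with pytest.raises(ValueError):
            log_prior(h, PerPIEffects({"a": np.zeros(2)}), PriorConfig())


class TestHyperparameters:
    def test_invalid_cholesky_rejected(self):
        bad = np.array([[1.0, 0.0], [0.9, 0.9]])  # row norm > 1
        with pytest.raises(ValueError):
            Hyperparameters(mu=np.zeros(2), zeta=np.ones(2),
                            omega_chol=bad, sigma=1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(mu=np.zeros(3), zeta=np.ones(2),
                            omega_chol=np.eye(3), sigma=1.0)
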