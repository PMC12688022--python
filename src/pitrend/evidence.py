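"""Marginal likelihood by Warp-III bridge sampling, and posterior model
probabilities.

The marginal likelihood (evidence) of a model is the integral of
likelihood times prior over all parameters.  Because the collapsed
posterior density of :mod:`pitrend.collapsed` carries every normalizing
constant and change-of-variables Jacobian, the evidence of the
hierarchical model equals the integral of ``exp(logp)`` over the
unconstrained parameter space, and bridge sampling can run directly on
the sampler's draws.

Warp-III preprocessing maps the posterior sample toward a standard
normal proposal: an affine moment-match (subtract the mean, whiten by a
Cholesky factor of the sample covariance) followed by a random
sign-flip, which symmetrizes the warped density about the origin and
removes residual skewness — the third moment, hence "warp-III".  The
optimal (Meng–Wong) bridge estimator is then iterated to a fixed point.
Estimates are averaged over independent repetitions (five by default),
each with a fresh posterior-sample split and proposal sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = ["EvidenceEstimate", "BridgeNonConvergence",
           "bridge_log_evidence", "log_marginal_likelihood",
           "posterior_model_probability"]


class BridgeNonConvergence(RuntimeError):
    """The bridge fixed-point iteration failed to converge; carries the
    last two iterates for inspection."""

    def __init__(self, last: float, previous: float, iterations: int):
        super().__init__(
            f"bridge iteration did not converge within {iterations} "
            f"iterations (last two iterates: {previous:.10g}, {last:.10g})")
        self.last = last
        self.previous = previous


@dataclass(frozen=True)
class EvidenceEstimate:
    """Log marginal likelihood: the mean over independent repetitions."""

    log_ml: float
    repetition_values: tuple[float, ...]
    convergence_iterations: tuple[int, ...]

    def __post_init__(self) -> None:
        if not np.isclose(self.log_ml,
                          float(np.mean(self.repetition_values))):
            raise ValueError("log_ml must equal the mean of the repetitions")

    @property
    def n_repetitions(self) -> int:
        return len(self.repetition_values)

    @property
    def sd(self) -> float:
        if self.n_repetitions < 2:
            return float("nan")
        return float(np.std(self.repetition_values, ddof=1))


def _bridge_iteration(l1: np.ndarray, l2: np.ndarray, tol: float,
                      max_iter: int) -> tuple[float, int]:
    """Optimal-bridge fixed point for log evidence.

    ``l1``: log q(xi) - log g(xi) at draws xi from the (warped) posterior;
    ``l2``: the same at draws from the proposal g.  Iterates the
    Meng-Wong update in log space until the log-evidence changes by less
    than ``tol`` in relative terms.
    """
    n1, n2 = len(l1), len(l2)
    log_s1 = math.log(n1 / (n1 + n2))
    log_s2 = math.log(n2 / (n1 + n2))
    log_r = float(logsumexp(l2) - math.log(n2))   # importance-sampling start
    for it in range(1, max_iter + 1):
        log_num = logsumexp(
            l2 - np.logaddexp(log_s1 + l2, log_s2 + log_r)) - math.log(n2)
        log_den = logsumexp(
            -np.logaddexp(log_s1 + l1, log_s2 + log_r)) - math.log(n1)
        log_r_new = log_num - log_den
        if abs(log_r_new - log_r) <= tol * max(1.0, abs(log_r_new)):
            return log_r_new, it
        log_r = log_r_new
    raise BridgeNonConvergence(log_r_new, log_r, max_iter)


def bridge_log_evidence(draws: np.ndarray,
                        log_density: Callable[[np.ndarray], float],
                        rng: np.random.Generator,
                        tol: float = 1e-10,
                        max_iter: int = 1000) -> tuple[float, int]:
    """One Warp-III bridge-sampling estimate of log integral exp(log_density).

    ``draws`` are posterior samples (rows) of the unnormalized density.
    Half the (permuted) draws moment-match the proposal, the other half
    enter the bridge; the proposal sample size matches the bridge half.
    """
    draws = np.asarray(draws, dtype=float)
    n, dim = draws.shape
    if n < 20:
        raise ValueError("need at least 20 posterior draws")
    perm = rng.permutation(n)
    half = n // 2
    fit, bridge = draws[perm[:half]], draws[perm[half:]]

    m = fit.mean(axis=0)
    cov = np.cov(fit.T, ddof=1).reshape(dim, dim)
    cov[np.diag_indices(dim)] += 1e-10 * np.trace(cov) / dim
    R = np.linalg.cholesky(cov)
    log_det_R = float(np.sum(np.log(np.diag(R))))

    def log_q_warped(xi: np.ndarray) -> np.ndarray:
        """log of the sign-symmetrized, moment-matched density at rows xi."""
        shift = xi @ R.T
        lp_plus = np.array([log_density(m + row) for row in shift])
        lp_minus = np.array([log_density(m - row) for row in shift])
        return log_det_R - math.log(2.0) + np.logaddexp(lp_plus, lp_minus)

    def log_g(xi: np.ndarray) -> np.ndarray:
        return -0.5 * np.sum(xi ** 2, axis=1) \
            - 0.5 * xi.shape[1] * math.log(2.0 * math.pi)

    signs = rng.choice([-1.0, 1.0], size=(len(bridge), 1))
    xi1 = signs * solve_triangular(R, (bridge - m).T, lower=True).T
    xi2 = rng.standard_normal((len(bridge), dim))

    l1 = log_q_warped(xi1) - log_g(xi1)
    l2 = log_q_warped(xi2) - log_g(xi2)
    keep = np.isfinite(l2)
    return _bridge_iteration(l1[keep], l2[keep], tol, max_iter)


def log_marginal_likelihood(samples, n_repetitions: int = 5,
                            seed: int = 0, tol: float = 1e-10,
                            max_iter: int = 1000,
                            max_draws: int = 4000) -> EvidenceEstimate:
    """Evidence of a fitted model, averaged over bridge repetitions.

    ``samples`` is a :class:`pitrend.inference.PosteriorSamples`; its
    unconstrained draws and collapsed density supply the bridge inputs.
    At most ``max_draws`` posterior draws enter each repetition (an
    evenly-thinned subset when more are available).
    """
    draws = samples.flat_theta()
    if len(draws) > max_draws:
        step = len(draws) / max_draws
        draws = draws[(np.arange(max_draws) * step).astype(int)]
    logp = samples.target.logp
    rng = np.random.default_rng(seed)
    values, iters = [], []
    for _ in range(n_repetitions):
        value, it = bridge_log_evidence(draws, logp, rng, tol=tol,
                                        max_iter=max_iter)
        values.append(value)
        iters.append(it)
    return EvidenceEstimate(log_ml=float(np.mean(values)),
                            repetition_values=tuple(values),
                            convergence_iterations=tuple(iters))


def posterior_model_probability(log_ml_p: float, log_ml_0: float) -> float:
    """P(M_p | data) against a single competitor under equal model priors.

    Computed stably in log space: exp(l_p) / (exp(l_p) + exp(l_0)).
    Infinite inputs degrade gracefully to probability 0 or 1.
    """
    if math.isnan(log_ml_p) or math.isnan(log_ml_0):
        raise ValueError("log marginal likelihoods must not be NaN")
    if math.isinf(log_ml_p) and math.isinf(log_ml_0):
        if log_ml_p < 0 and log_ml_0 < 0:
            raise ValueError("both evidences are zero")
        if log_ml_p > 0 and log_ml_0 > 0:
            raise ValueError("both evidences are infinite")
    diff = log_ml_0 - log_ml_p
    if diff > 0:
        return math.exp(-diff) / (1.0 + math.exp(-diff)) if diff < 745 else 0.0
    return 1.0 / (1.0 + math.exp(diff))
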