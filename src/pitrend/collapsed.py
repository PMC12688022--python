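"""Collapsed posterior of the hierarchical score-change model.

The model's Gaussian structure lets the per-PI effect vectors integrate
out in closed form: for PI ``i`` with design matrix ``X_i`` and observed
changes ``d_i``,

    d_i | mu, Sigma, sigma  ~  Normal( X_i mu,  X_i Sigma X_i' + sigma^2 I ).

Sampling therefore runs over the hyperparameters only — a few dozen
dimensions free of the funnel geometry that plagues centered hierarchical
parameterizations — and the per-PI effects are recovered afterwards from
their exact Gaussian conditionals.  The marginal likelihood of the
collapsed parameter space equals that of the full model, so the same
density object serves the bridge-sampling evidence estimator.

The log posterior and its analytic gradient are evaluated over all PIs
at once: designs are zero-padded to a common assessment count and the
padding's spurious contributions (which affect only the log-determinant
and the residual-variance trace) are subtracted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from ._transforms import CorrCholTransform, n_corr_params
from .model import (
    Hyperparameters,
    ModelSpec,
    PriorConfig,
    ScoreChangeObservation,
    build_design_matrix,
    half_normal_logpdf,
    half_t_logpdf,
    lkj_log_normalizer,
)

__all__ = ["CollapsedPosterior"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class _GroupedData:
    pi_ids: tuple[str, ...]
    X: np.ndarray        # (G, n_max, p), zero rows beyond each group's count
    d: np.ndarray        # (G, n_max)
    n_obs: np.ndarray    # (G,) true observation counts
    n_total: int
    n_pad_total: int


def _group(observations: Sequence[ScoreChangeObservation],
           spec: ModelSpec) -> _GroupedData:
    by_pi: dict[str, list[ScoreChangeObservation]] = {}
    for obs in observations:
        by_pi.setdefault(obs.pi_id, []).append(obs)
    pi_ids = tuple(sorted(by_pi))
    counts = np.array([len(by_pi[k]) for k in pi_ids])
    n_max = int(counts.max())
    p = spec.dim
    X = np.zeros((len(pi_ids), n_max, p))
    d = np.zeros((len(pi_ids), n_max))
    for g, pid in enumerate(pi_ids):
        grp = by_pi[pid]
        X[g, :len(grp), :] = build_design_matrix(grp, spec)
        d[g, :len(grp)] = [o.d for o in grp]
    n_total = int(counts.sum())
    return _GroupedData(pi_ids, X, d, counts, n_total,
                        int(len(pi_ids) * n_max - n_total))


class CollapsedPosterior:
    """Log posterior density (and gradient) over unconstrained
    hyperparameters, with the per-PI effects integrated out.

    Parameter layout: ``theta = [mu (p), log zeta (p), corr (p(p-1)/2),
    log sigma]``.  The density includes every prior normalizing constant
    and change-of-variables Jacobian, so ``exp(logp)`` integrates to the
    model's marginal likelihood.
    """

    def __init__(self, observations: Sequence[ScoreChangeObservation],
                 spec: ModelSpec, priors: PriorConfig | None = None):
        if not observations:
            raise ValueError("no score-change observations supplied")
        self.spec = spec
        self.priors = priors or PriorConfig()
        self.data = _group(observations, spec)
        self.p = spec.dim
        self.corr = CorrCholTransform(self.p)
        self.n_params = 2 * self.p + n_corr_params(self.p) + 1
        self._mu_scales = self.priors.mu_scales(self.p)
        # constant pieces of the log density
        pc = self.priors
        self._const = (
            - 0.5 * self.data.n_total * _LOG_2PI
            - float(np.sum(0.5 * _LOG_2PI + np.log(self._mu_scales)))
            + self.p * (math.log(2.0)
                        + float(special.gammaln((pc.zeta_df + 1) / 2.0)
                                - special.gammaln(pc.zeta_df / 2.0)
                                - 0.5 * math.log(pc.zeta_df * math.pi)
                                - math.log(pc.zeta_scale)))
            + math.log(2.0) - 0.5 * _LOG_2PI - math.log(pc.sigma_scale)
            - lkj_log_normalizer(self.p, pc.lkj_shape)
        )

    # -- packing ----------------------------------------------------------
    def split(self, theta: np.ndarray):
        p = self.p
        m = n_corr_params(p)
        return (theta[:p], theta[p:2 * p], theta[2 * p:2 * p + m],
                theta[2 * p + m])

    def unpack(self, theta: np.ndarray) -> Hyperparameters:
        mu, u, y, v = self.split(np.asarray(theta, dtype=float))
        L, _, _ = self.corr.forward(y)
        return Hyperparameters(mu=mu.copy(), zeta=np.exp(u),
                               omega_chol=L, sigma=float(np.exp(v)))

    def pack(self, h: Hyperparameters) -> np.ndarray:
        if h.dim != self.p:
            raise ValueError("hyperparameter dimension mismatch")
        if np.any(h.zeta <= 0):
            raise ValueError("zeta must be strictly positive to map to the "
                             "unconstrained space")
        return np.concatenate([
            h.mu, np.log(h.zeta), self.corr.inverse(h.omega_chol),
            [math.log(h.sigma)],
        ])

    # -- density ----------------------------------------------------------
    def logp(self, theta: np.ndarray) -> float:
        return self._eval(theta, with_grad=False)[0]

    def logp_grad(self, theta: np.ndarray):
        return self._eval(theta, with_grad=True)

    def _eval(self, theta: np.ndarray, with_grad: bool):
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 600.0:
            # far outside any plausible region (e.g. a divergent
            # Hamiltonian trajectory): reject without evaluating
            bad = -np.inf
            return (bad, np.full(self.n_params, np.nan)) if with_grad \
                else (bad, None)
        mu, u, y, v = self.split(theta)
        zeta = np.exp(u)
        sigma = float(np.exp(v))
        sigma2 = sigma * sigma
        L, corr_jac, caches = self.corr.forward(y)
        B = zeta[:, None] * L                      # covariance Cholesky
        Sigma = B @ B.T
        X, d, n_obs = self.data.X, self.data.d, self.data.n_obs
        G, n_max, p = X.shape

        # marginal covariance per PI: C = X Sigma X' + sigma^2 I
        XS = X @ Sigma                              # (G, n_max, p)
        C = XS @ np.swapaxes(X, 1, 2)
        idx = np.arange(n_max)
        C[:, idx, idx] += sigma2

        if not np.all(np.isfinite(C)):
            bad = -np.inf
            return (bad, np.full(self.n_params, np.nan)) if with_grad \
                else (bad, None)
        sign, logdet = np.linalg.slogdet(C)
        if np.any(sign <= 0):
            bad = -np.inf
            return (bad, np.full(self.n_params, np.nan)) if with_grad else (bad, None)
        Cinv = np.linalg.inv(C)
        r = d - X @ mu                              # padded slots are 0
        a = np.einsum("gij,gj->gi", Cinv, r)
        quad = float(np.einsum("gi,gi->", r, a))
        # padded slots add log(sigma^2) each to logdet and nothing to quad;
        # the 2pi constant (true n_total only) lives in self._const
        loglik = (-0.5 * float(logdet.sum())
                  + 0.5 * self.data.n_pad_total * math.log(sigma2)
                  - 0.5 * quad)

        pc = self.priors
        lp = (loglik
              - 0.5 * float(np.sum((mu / self._mu_scales) ** 2))
              - 0.5 * (pc.zeta_df + 1.0)
              * float(np.sum(np.log1p((zeta / pc.zeta_scale) ** 2 / pc.zeta_df)))
              + float(np.sum(u))                       # d zeta / d u
              - 0.5 * (sigma / pc.sigma_scale) ** 2
              + v                                      # d sigma / d v
              + float(np.sum((self.p - np.arange(2, self.p + 1)
                              + 2.0 * pc.lkj_shape - 2.0)
                             * np.log(np.diag(L)[1:])))
              + corr_jac
              + self._const)

        if not with_grad:
            return lp, None
        if not np.isfinite(lp):
            return lp, np.full(self.n_params, np.nan)

        # ---- gradient ----------------------------------------------------
        # A_g = d loglik / d C_g (symmetric-variation gradient)
        A = 0.5 * (np.einsum("gi,gj->gij", a, a) - Cinv)
        grad_mu = np.einsum("gij,gi->j", X, a) - mu / self._mu_scales ** 2
        Gmat = np.einsum("gni,gnm,gmj->ij", X, A, X)   # d loglik / d Sigma
        # sigma^2 appears on the diagonal of C; padded slots corrected
        trA = float(np.einsum("gii->", A)) + 0.5 * self.data.n_pad_total / sigma2
        dlp_dsigma = 2.0 * sigma * trA - sigma / pc.sigma_scale ** 2
        grad_v = dlp_dsigma * sigma + 1.0

        B_bar = 2.0 * Gmat @ B                          # Sigma = B B'
        B_bar = np.tril(B_bar)
        zeta_bar = np.sum(B_bar * L, axis=1)
        L_bar = B_bar * zeta[:, None]
        # LKJ density term on the diagonal of L
        diag_idx = np.arange(1, self.p)
        L_bar[diag_idx, diag_idx] += (
            (self.p - np.arange(2, self.p + 1) + 2.0 * pc.lkj_shape - 2.0)
            / np.diag(L)[1:])
        grad_y = self.corr.vjp(L, caches, L_bar, include_jacobian=True)
        dprior_dzeta = -(pc.zeta_df + 1.0) * zeta / (
            pc.zeta_df * pc.zeta_scale ** 2 + zeta ** 2)
        grad_u = (zeta_bar + dprior_dzeta) * zeta + 1.0

        grad = np.concatenate([grad_mu, grad_u, grad_y, [grad_v]])
        return lp, grad

    # -- per-PI effect recovery -------------------------------------------
    def conditional_effect_moments(self, h: Hyperparameters):
        """Exact Gaussian conditional (mean, covariance) of each beta_i
        given the hyperparameters and that PI's observed changes."""
        Sigma = h.covariance
        Sigma_inv = np.linalg.inv(Sigma)
        sigma2 = h.sigma ** 2
        means, covs = [], []
        for g, pid in enumerate(self.data.pi_ids):
            n = self.data.n_obs[g]
            Xg = self.data.X[g, :n, :]
            dg = self.data.d[g, :n]
            prec = Sigma_inv + Xg.T @ Xg / sigma2
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + cov.T)
            mean = cov @ (Sigma_inv @ h.mu + Xg.T @ dg / sigma2)
            means.append(mean)
            covs.append(cov)
        return self.data.pi_ids, np.array(means), np.array(covs)

    def sample_effects(self, h: Hyperparameters,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
        """One draw of every beta_i from its conditional posterior."""
        pi_ids, means, covs = self.conditional_effect_moments(h)
        out = {}
        for pid, mean, cov in zip(pi_ids, means, covs):
            chol = np.linalg.cholesky(cov)
            out[pid] = mean + chol @ rng.standard_normal(self.p)
        return out

    def sample_effects_batch(self, mu: np.ndarray, zeta: np.ndarray,
                             omega_chol: np.ndarray, sigma: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
        """Conditional effect draws for a whole batch of posterior draws.

        Inputs are (N, p), (N, p), (N, p, p) and (N,) arrays; the result is
        (N, G, p) with one beta_i draw per posterior draw and PI, from the
        exact Gaussian conditional given that PI's observed changes.
        """
        N, p = mu.shape
        B = zeta[:, :, None] * omega_chol                 # (N, p, p)
        Sigma = B @ np.swapaxes(B, 1, 2)
        Sigma_inv = np.linalg.inv(Sigma)
        sigma2 = (sigma ** 2)[:, None, None]
        rhs_mu = np.einsum("nij,nj->ni", Sigma_inv, mu)
        G = len(self.data.pi_ids)
        out = np.empty((N, G, p))
        for g in range(G):
            n = self.data.n_obs[g]
            Xg = self.data.X[g, :n, :]
            dg = self.data.d[g, :n]
            prec = Sigma_inv + (Xg.T @ Xg)[None, :, :] / sigma2
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
            rhs = rhs_mu + (Xg.T @ dg)[None, :] / sigma2[:, :, 0]
            mean = np.einsum("nij,nj->ni", cov, rhs)
            chol = np.linalg.cholesky(cov)
            z = rng.standard_normal((N, p))
            out[:, g, :] = mean + np.einsum("nij,nj->ni", chol, z)
        return out
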