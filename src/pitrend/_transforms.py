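"""Unconstrained reparameterizations used by the sampler and the evidence
estimator.

The hierarchical model's constrained parameters map to an unconstrained
vector ``theta`` as

    theta = [ mu (p) | u = log zeta (p) | y (p(p-1)/2) | v = log sigma ]

where ``y`` parameterizes the correlation Cholesky factor through
canonical partial correlations ``z = tanh(y)`` built row by row (the
standard transform for Cholesky factors of correlation matrices).  All
log-Jacobian terms are provided so that densities over ``theta``
integrate to the same mass as over the constrained space — a requirement
for marginal-likelihood estimation, not just for sampling.

Gradients are hand-coded reverse-mode sweeps; they are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CorrCholTransform", "n_corr_params"]


def n_corr_params(dim: int) -> int:
    return dim * (dim - 1) // 2


@dataclass
class _RowCache:
    z: np.ndarray     # partial correlations of this row
    w: np.ndarray     # remaining-norm factors sqrt(1 - c_j) before column j


class CorrCholTransform:
    """Bijection between R^(p(p-1)/2) and p x p correlation Cholesky factors."""

    def __init__(self, dim: int):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.n_params = n_corr_params(dim)

    # -- forward ----------------------------------------------------------
    def forward(self, y: np.ndarray):
        """Map unconstrained ``y`` to (L, log_jacobian, cache).

        The log-Jacobian is log |dL/dy| of the free (below-diagonal)
        entries: sum over entries of log(1 - z^2) + log w.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters")
        p = self.dim
        L = np.zeros((p, p))
        L[0, 0] = 1.0
        log_jac = 0.0
        caches: list[_RowCache] = []
        pos = 0
        for i in range(1, p):
            # clip away from +-1 so extreme (divergent-trajectory) inputs
            # yield a finite-but-huge penalty instead of a domain error
            z = np.clip(np.tanh(y[pos:pos + i]), -1.0 + 1e-12, 1.0 - 1e-12)
            pos += i
            w = np.empty(i)
            c = 0.0
            for j in range(i):
                wj = math.sqrt(max(1.0 - c, 1e-300))
                w[j] = wj
                L[i, j] = z[j] * wj
                c += L[i, j] ** 2
                log_jac += math.log1p(-z[j] ** 2) + math.log(wj)
            L[i, i] = math.sqrt(max(1.0 - c, 1e-300))
            caches.append(_RowCache(z=z, w=w))
        return L, log_jac, caches

    # -- reverse-mode -----------------------------------------------------
    def vjp(self, L: np.ndarray, caches, L_bar: np.ndarray,
            include_jacobian: bool = True) -> np.ndarray:
        """Gradient wrt ``y`` of  F = f(L(y)) [+ log_jacobian(y)]
        given ``L_bar = dF/dL`` (lower triangle incl. diagonal)."""
        p = self.dim
        y_bar = np.zeros(self.n_params)
        pos = self.n_params
        for i in range(p - 1, 0, -1):
            cache = caches[i - 1]
            z, w = cache.z, cache.w
            pos -= i
            row_bar = np.empty(i)
            # c_i feeds only the diagonal entry L_ii = sqrt(1 - c_i)
            c_bar = L_bar[i, i] * (-0.5 / L[i, i])
            for j in range(i - 1, -1, -1):
                lij_bar = L_bar[i, j] + c_bar * 2.0 * L[i, j]
                w_bar = lij_bar * z[j]
                z_bar = lij_bar * w[j]
                if include_jacobian:
                    w_bar += 1.0 / w[j]
                    z_bar += -2.0 * z[j] / (1.0 - z[j] ** 2)
                # w_j = sqrt(1 - c_j): both the pass-through and the w path
                c_bar = c_bar + w_bar * (-0.5 / w[j])
                row_bar[j] = z_bar * (1.0 - z[j] ** 2)
            y_bar[pos:pos + i] = row_bar
        return y_bar

    # -- inverse ----------------------------------------------------------
    def inverse(self, L: np.ndarray) -> np.ndarray:
        """Unconstrained coordinates of a valid correlation Cholesky factor."""
        L = np.asarray(L, dtype=float)
        p = self.dim
        y = np.empty(self.n_params)
        pos = 0
        for i in range(1, p):
            c = 0.0
            for j in range(i):
                wj = math.sqrt(max(1.0 - c, 1e-300))
                z = np.clip(L[i, j] / wj, -1 + 1e-12, 1 - 1e-12)
                y[pos] = np.arctanh(z)
                pos += 1
                c += L[i, j] ** 2
        return y
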