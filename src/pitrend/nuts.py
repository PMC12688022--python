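"""No-U-Turn sampler over a differentiable unnormalized log density.

A self-contained implementation of dynamic Hamiltonian Monte Carlo in the
now-standard form: multinomial sampling over the trajectory, doubling
until the first sub-U-turn, dual-averaging step-size adaptation toward a
target acceptance statistic, and windowed estimation of a diagonal mass
matrix during warmup.  The only requirement on the target is a callable
returning ``(logp, grad)`` at a point of R^dim.

The implementation favours clarity over micro-optimization; the model
densities it drives are a few dozen dimensions with analytic gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "ChainStats", "nuts_chain"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass(frozen=True)
class NutsConfig:
    n_warmup: int = 500
    n_draws: int = 500
    target_accept: float = 0.9
    max_tree_depth: int = 10
    init_buffer_frac: float = 0.15
    term_buffer_frac: float = 0.1
    dense_mass: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.n_warmup < 20 or self.n_draws < 1:
            raise ValueError("n_warmup >= 20 and n_draws >= 1 required")


@dataclass
class ChainStats:
    divergences: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    tree_depths: list = field(default_factory=list)


@dataclass
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    q_prop: np.ndarray
    logp_prop: float
    log_w: float
    sum_metro: float
    n_states: int
    stop: bool
    diverged: bool


class _Hamiltonian:
    """Kinetic energy with a diagonal or dense inverse mass matrix.

    A dense metric (the regularized sample covariance of warmup draws)
    absorbs posterior correlations — essential here because raw-unit
    predictors (days, days^2, scores) give strongly correlated
    coefficients.
    """

    def __init__(self, logp_grad: LogpGrad, inv_mass: np.ndarray):
        self.logp_grad = logp_grad
        self.inv_mass = np.asarray(inv_mass, dtype=float)
        self.dense = self.inv_mass.ndim == 2
        if self.dense:
            # momenta ~ N(0, M) with M = inv_mass^-1: p = L^-T z where
            # inv_mass = L L^T
            chol = np.linalg.cholesky(self.inv_mass)
            self._momentum_transform = np.linalg.inv(chol).T
        else:
            self._momentum_transform = 1.0 / np.sqrt(self.inv_mass)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_mass @ p if self.dense else self.inv_mass * p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            value = 0.5 * float(p @ self.velocity(p))
        return value if np.isfinite(value) else np.inf

    def draw_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.inv_mass.shape[0])
        return (self._momentum_transform @ z if self.dense
                else self._momentum_transform * z)

    def leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.velocity(p)
        logp, grad = self.logp_grad(q)
        if not np.all(np.isfinite(grad)):
            return q, p, grad, -np.inf
        p = p + 0.5 * eps * grad
        return q, p, grad, logp


def _uturn(ham: _Hamiltonian, tree: _Tree) -> bool:
    dq = tree.q_plus - tree.q_minus
    return (float(dq @ ham.velocity(tree.p_minus)) < 0
            or float(dq @ ham.velocity(tree.p_plus)) < 0)


def _build_tree(ham, q, p, grad, depth, direction, eps, h0, rng) -> _Tree:
    if depth == 0:
        q1, p1, g1, logp1 = ham.leapfrog(q, p, grad, direction * eps)
        h1 = -logp1 + ham.kinetic(p1) if np.isfinite(logp1) else np.inf
        log_w = h0 - h1
        diverged = not np.isfinite(h1) or (h1 - h0) > _DIVERGENCE_THRESHOLD
        metro = 0.0 if diverged else min(1.0, math.exp(min(0.0, log_w)))
        return _Tree(q1, p1, g1, q1, p1, g1, q1, logp1,
                     -np.inf if diverged else log_w,
                     metro, 1, diverged, diverged)
    first = _build_tree(ham, q, p, grad, depth - 1, direction, eps, h0, rng)
    if first.stop:
        return first
    if direction > 0:
        second = _build_tree(ham, first.q_plus, first.p_plus, first.g_plus,
                             depth - 1, direction, eps, h0, rng)
        first.q_plus, first.p_plus, first.g_plus = (
            second.q_plus, second.p_plus, second.g_plus)
    else:
        second = _build_tree(ham, first.q_minus, first.p_minus, first.g_minus,
                             depth - 1, direction, eps, h0, rng)
        first.q_minus, first.p_minus, first.g_minus = (
            second.q_minus, second.p_minus, second.g_minus)
    total = np.logaddexp(first.log_w, second.log_w)
    if np.isfinite(second.log_w) and \
            math.log(rng.uniform()) < second.log_w - total:
        first.q_prop, first.logp_prop = second.q_prop, second.logp_prop
    first.log_w = total
    first.sum_metro += second.sum_metro
    first.n_states += second.n_states
    first.diverged = first.diverged or second.diverged
    first.stop = second.stop or _uturn(ham, first)
    return first


def _transition(ham, q, grad, logp, eps, max_depth, rng):
    p0 = ham.draw_momentum(rng)
    h0 = -logp + ham.kinetic(p0)
    tree = _Tree(q, p0, grad, q, p0, grad, q, logp, 0.0, 0.0, 1, False, False)
    depth = 0
    sum_metro, n_states = 0.0, 0
    diverged = False
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            sub = _build_tree(ham, tree.q_plus, tree.p_plus, tree.g_plus,
                              depth, direction, eps, h0, rng)
        else:
            sub = _build_tree(ham, tree.q_minus, tree.p_minus, tree.g_minus,
                              depth, direction, eps, h0, rng)
        sum_metro += sub.sum_metro
        n_states += sub.n_states
        diverged = diverged or sub.diverged
        if sub.stop:
            break
        # biased progressive sampling toward the new subtree
        if math.log(rng.uniform()) < sub.log_w - tree.log_w:
            tree.q_prop, tree.logp_prop = sub.q_prop, sub.logp_prop
        if direction > 0:
            tree.q_plus, tree.p_plus, tree.g_plus = (
                sub.q_plus, sub.p_plus, sub.g_plus)
        else:
            tree.q_minus, tree.p_minus, tree.g_minus = (
                sub.q_minus, sub.p_minus, sub.g_minus)
        tree.log_w = np.logaddexp(tree.log_w, sub.log_w)
        depth += 1
        if _uturn(ham, tree):
            break
    accept = sum_metro / max(n_states, 1)
    return tree.q_prop, tree.logp_prop, accept, depth, diverged


def _find_initial_step(ham, q, grad, logp, rng) -> float:
    eps = 1.0
    p0 = ham.draw_momentum(rng)
    h0 = -logp + ham.kinetic(p0)
    _, p1, _, logp1 = ham.leapfrog(q, p0, grad, eps)
    h1 = -logp1 + ham.kinetic(p1) if np.isfinite(logp1) else np.inf
    direction = 1 if (h0 - h1) > math.log(0.5) else -1
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, _, logp1 = ham.leapfrog(q, p0, grad, eps)
        h1 = -logp1 + ham.kinetic(p1) if np.isfinite(logp1) else np.inf
        crossed = (h0 - h1) > math.log(0.5)
        if (direction == 1) != crossed:
            break
    return eps


def _adapt_windows(n_warmup: int, cfg: NutsConfig):
    """(start, end) slices of warmup used to estimate the metric."""
    init = max(int(cfg.init_buffer_frac * n_warmup), 10)
    term = max(int(cfg.term_buffer_frac * n_warmup), 10)
    windows = []
    start, size = init, max((n_warmup - init - term) // 4, 10)
    while start + size <= n_warmup - term:
        end = start + size
        if n_warmup - term - end < size * 2:
            end = n_warmup - term
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def nuts_chain(logp_grad: LogpGrad, q0: np.ndarray, cfg: NutsConfig,
               rng: np.random.Generator,
               init_metric: np.ndarray | None = None):
    """Run one NUTS chain; returns (draws, ChainStats).

    ``init_metric`` optionally seeds the inverse mass matrix (diagonal
    vector or dense matrix), e.g. from a Laplace approximation; warmup
    windows keep re-estimating it from the chain.
    """
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError(
            f"non-finite log density at the initial point (logp={logp}); "
            f"initial parameters: {q!r}")
    dim = len(q)
    inv_mass = np.ones(dim) if init_metric is None else init_metric
    ham = _Hamiltonian(logp_grad, inv_mass)
    eps = _find_initial_step(ham, q, grad, logp, rng)

    # dual averaging state
    mu_da = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _adapt_windows(cfg.n_warmup, cfg)
    window_idx = 0
    window_samples: list[np.ndarray] = []
    stats = ChainStats()
    accepts = []
    da_count = 0

    draws = np.empty((cfg.n_draws, dim))
    for it in range(cfg.n_warmup + cfg.n_draws):
        warming = it < cfg.n_warmup
        q, logp, accept, depth, diverged = _transition(
            ham, q, grad, logp, eps, cfg.max_tree_depth, rng)
        logp, grad = logp_grad(q)
        if warming:
            da_count += 1
            h_bar = ((1.0 - 1.0 / (da_count + t0)) * h_bar
                     + (cfg.target_accept - accept) / (da_count + t0))
            log_eps = mu_da - math.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if window_idx < len(windows):
                start, end = windows[window_idx]
                if start <= it < end:
                    window_samples.append(q.copy())
                if it == end - 1 and len(window_samples) > 4:
                    arr = np.array(window_samples)
                    n = len(window_samples)
                    shrink = n / (n + 5.0)
                    if cfg.dense_mass and n >= dim + 5:
                        cov = np.cov(arr.T, ddof=1).reshape(dim, dim)
                        metric = shrink * cov + (1.0 - shrink) * 1e-3 * np.eye(dim)
                        metric[np.diag_indices(dim)] += 1e-8
                    else:
                        var = np.var(arr, axis=0, ddof=1)
                        metric = shrink * var + (1.0 - shrink) * 1e-3
                    ham = _Hamiltonian(logp_grad, metric)
                    window_samples = []
                    window_idx += 1
                    # restart step-size adaptation for the new metric
                    eps = _find_initial_step(ham, q, grad, logp, rng)
                    mu_da = math.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == cfg.n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            draws[it - cfg.n_warmup] = q
            accepts.append(accept)
            stats.tree_depths.append(depth)
            if diverged:
                stats.divergences += 1
    stats.step_size = eps
    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    return draws, stats
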