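"""Hierarchical Bayesian regression of DESIGN-R 2020 score changes.

The modelled unit is one observed change ``d_i(t, s) = y_{i,t+s} - y_{i,t}``
of the total severity score of pressure injury ``i`` between two
consecutive assessments ``s`` days apart.  Each change is regressed on a
design row

    [1, s, (s^2 if enabled), x_1(t), ..., x_k(t)]

with a coefficient vector ``beta_i`` specific to the lesion:

    d_i(t, s) = x(t, s)' beta_i + eps,        eps  ~ Normal(0, sigma^2)
    beta_i    ~ MultiNormal(mu, Sigma),       Sigma = B B',  B = diag(zeta) L

where ``L`` is the Cholesky factor of a correlation matrix.  ``mu`` carries
the population-level (fixed) effects, ``zeta`` the between-lesion (random)
effect scales.

Priors: ``sigma ~ HalfNormal(100)``; ``mu_intercept ~ Normal(0, 10)``;
remaining ``mu`` entries ``~ Normal(0, 1)``; each ``zeta ~ HalfStudentT(4,
0, 1)``; ``L ~ LKJCholesky(4)``.  Truncated densities include their
renormalization constants so that marginal likelihoods are on an absolute
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "DURATION_NEXT",
    "DURATION_NEXT_SQ",
    "KNOWN_PREDICTORS",
    "ScoreChangeObservation",
    "ModelSpec",
    "PriorConfig",
    "Hyperparameters",
    "PerPIEffects",
    "build_design_row",
    "build_design_matrix",
    "assemble_covariance_chol",
    "log_likelihood",
    "log_prior",
    "lkj_cholesky_logpdf",
    "lkj_log_normalizer",
    "half_t_logpdf",
    "half_normal_logpdf",
]

DURATION_NEXT = "duration_next"
DURATION_NEXT_SQ = "duration_next_sq"
DURATION_DAY0 = "duration_day0"
DURATION_DAY0_SQ = "duration_day0_sq"

#: predictors the observation builder knows how to derive; any further
#: binary covariate column present in the data is also accepted by name.
KNOWN_PREDICTORS = (
    DURATION_DAY0,
    DURATION_DAY0_SQ,
    "baseline_score",
    "latest_score",
    "age",
    "e_large", "e_small", "s_large", "s_small", "i_large", "i_small",
    "g_large", "g_small", "n_large", "n_small", "p_large", "p_small",
    "posture_bed", "posture_chair", "bony_prominence", "joint_contracture",
    "malnutrition", "wet_skin", "edema", "skin_tear",
    "dementia", "diabetes", "liver_disease", "cardiovascular_disease",
    "cerebrovascular_disease", "respiratory_disease", "cancer",
)


@dataclass(frozen=True)
class ScoreChangeObservation:
    """One modelled score change of one pressure injury.

    ``duration_day0`` is the elapsed time (days) from the first assessment
    to the assessment the prediction is made from; ``duration_next`` is the
    gap (days) to the next assessment; ``d`` is the observed change in the
    total score over that gap.  ``covariates`` holds every named predictor
    value available at prediction time.
    """

    pi_id: str
    duration_day0: float
    duration_next: float
    d: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def covariate(self, name: str) -> float:
        if name == DURATION_DAY0:
            return float(self.duration_day0)
        if name == DURATION_DAY0_SQ:
            return float(self.duration_day0) ** 2
        try:
            return float(self.covariates[name])
        except KeyError:
            raise KeyError(
                f"observation for PI {self.pi_id!r} lacks covariate {name!r}"
            ) from None


@dataclass(frozen=True)
class ModelSpec:
    """The predictor set defining one candidate model.

    Every model contains an intercept and the assessment gap ``s``
    (DurationForNext); the base model contains nothing else.  The quadratic
    gap term ``s^2`` is a model-level flag rather than an ordinary
    predictor because the hierarchical mean vector either includes or
    excludes it wholesale.  ``predictors`` lists the remaining covariates
    in design order.
    """

    predictors: tuple[str, ...] = ()
    include_quadratic_duration: bool = False

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("predictor names must be unique")
        for name in (DURATION_NEXT, DURATION_NEXT_SQ):
            if name in self.predictors:
                raise ValueError(
                    f"{name} is part of the base structure; use "
                    "include_quadratic_duration for the squared term")

    @property
    def column_names(self) -> tuple[str, ...]:
        cols = ["intercept", DURATION_NEXT]
        if self.include_quadratic_duration:
            cols.append(DURATION_NEXT_SQ)
        cols.extend(self.predictors)
        return tuple(cols)

    @property
    def dim(self) -> int:
        return len(self.column_names)

    def with_predictor(self, name: str) -> "ModelSpec":
        """Return the spec extended by one screenable candidate."""
        if name == DURATION_NEXT_SQ:
            return replace(self, include_quadratic_duration=True)
        return replace(self, predictors=self.predictors + (name,))

    def label(self) -> str:
        return "+".join(self.column_names[1:]) or "intercept"

    @classmethod
    def base(cls) -> "ModelSpec":
        """Duration-only base model M0."""
        return cls()

    @classmethod
    def published_best_structure(cls) -> "ModelSpec":
        """The predictor structure selected on the full training data:
        age, both durations with their squares, and the baseline total."""
        return cls(
            predictors=(DURATION_DAY0, DURATION_DAY0_SQ, "baseline_score",
                        "age"),
            include_quadratic_duration=True,
        )


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the weakly-informative priors (all on raw data units)."""

    sigma_scale: float = 100.0
    mu_slope_scale: float = 1.0
    mu_intercept_scale: float = 10.0
    zeta_df: float = 4.0
    zeta_scale: float = 1.0
    lkj_shape: float = 4.0

    def __post_init__(self) -> None:
        if min(self.sigma_scale, self.mu_slope_scale, self.mu_intercept_scale,
               self.zeta_df, self.zeta_scale, self.lkj_shape) <= 0:
            raise ValueError("all prior scales/shapes must be positive")

    def mu_scales(self, dim: int) -> np.ndarray:
        scales = np.full(dim, self.mu_slope_scale)
        scales[0] = self.mu_intercept_scale
        return scales


@dataclass(frozen=True)
class Hyperparameters:
    """Population-level parameters (mu, zeta, Omega-Cholesky, sigma)."""

    mu: np.ndarray
    zeta: np.ndarray
    omega_chol: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        zeta = np.asarray(self.zeta, dtype=float)
        L = np.asarray(self.omega_chol, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "zeta", zeta)
        object.__setattr__(self, "omega_chol", L)
        p = mu.shape[0]
        if zeta.shape != (p,) or L.shape != (p, p):
            raise ValueError("mu, zeta and omega_chol dimensions disagree")
        if np.any(zeta < 0):
            raise ValueError("zeta entries must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.allclose(L, np.tril(L)):
            raise ValueError("omega_chol must be lower triangular")
        if not np.allclose((L ** 2).sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("omega_chol rows must have unit norm")

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    @property
    def covariance_chol(self) -> np.ndarray:
        return assemble_covariance_chol(self.zeta, self.omega_chol)

    @property
    def covariance(self) -> np.ndarray:
        B = self.covariance_chol
        return B @ B.T


@dataclass(frozen=True)
class PerPIEffects:
    """Per-lesion coefficient vectors beta_i keyed by PI identifier."""

    beta: Mapping[str, np.ndarray]

    def require(self, pi_id: str) -> np.ndarray:
        try:
            return np.asarray(self.beta[pi_id], dtype=float)
        except KeyError:
            raise KeyError(f"no effect vector for PI {pi_id!r}") from None


def build_design_row(obs: ScoreChangeObservation, spec: ModelSpec) -> np.ndarray:
    """Covariate row [1, s, (s^2), x_1, ..., x_k] for one observation."""
    s = float(obs.duration_next)
    row = [1.0, s]
    if spec.include_quadratic_duration:
        row.append(s * s)
    for name in spec.predictors:
        row.append(obs.covariate(name))
    return np.asarray(row, dtype=float)


def build_design_matrix(observations: Sequence[ScoreChangeObservation],
                        spec: ModelSpec) -> np.ndarray:
    if not observations:
        return np.empty((0, spec.dim))
    return np.vstack([build_design_row(o, spec) for o in observations])


def assemble_covariance_chol(zeta: np.ndarray, omega_chol: np.ndarray) -> np.ndarray:
    """Covariance Cholesky factor diag(zeta) @ L from scales and correlation."""
    zeta = np.asarray(zeta, dtype=float)
    L = np.asarray(omega_chol, dtype=float)
    if np.any(zeta < 0):
        raise ValueError("zeta entries must be non-negative")
    if zeta.shape[0] != L.shape[0] or L.shape[0] != L.shape[1]:
        raise ValueError("dimension mismatch between zeta and omega_chol")
    return zeta[:, None] * L


# ---------------------------------------------------------------------------
# densities

_LOG_2PI = math.log(2.0 * math.pi)


def half_normal_logpdf(x: float, scale: float) -> float:
    """log density of |Normal(0, scale^2)| at x >= 0 (with the x2 constant)."""
    if x < 0:
        return -np.inf
    return math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale) \
        - 0.5 * (x / scale) ** 2


def half_t_logpdf(x: np.ndarray, df: float, scale: float = 1.0) -> np.ndarray:
    """log density of a positive (folded at 0) Student-t, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, -np.inf,
                   math.log(2.0) + stats.t.logpdf(x, df, scale=scale))
    return out


def lkj_log_normalizer(dim: int, shape: float) -> float:
    """log of the LKJ normalizing constant c_K(eta).

    The LKJ density over K x K correlation matrices is
    ``det(Omega)^(eta-1) / c_K(eta)`` with

        c_K(eta) = prod_{k=1}^{K-1} [ 2^(2 eta - 2 + K - k)
                                      B(a_k, a_k) ]^(K-k),
        a_k = eta + (K - 1 - k) / 2.
    """
    log_c = 0.0
    for k in range(1, dim):
        a = shape + (dim - 1 - k) / 2.0
        log_c += (dim - k) * ((2.0 * shape - 2.0 + dim - k) * math.log(2.0)
                              + special.betaln(a, a))
    return log_c


def lkj_cholesky_logpdf(L: np.ndarray, shape: float) -> float:
    """log density of the LKJ distribution in Cholesky parameterization.

    ``L`` is lower triangular with unit-norm rows;
    log f = -log c_K(eta) + sum_{k=2}^K (K - k + 2 eta - 2) log L_kk.
    """
    L = np.asarray(L, dtype=float)
    K = L.shape[0]
    diag = np.diag(L)[1:]
    if np.any(diag <= 0):
        return -np.inf
    exponents = np.array([K - k + 2.0 * shape - 2.0 for k in range(2, K + 1)])
    return float(np.sum(exponents * np.log(diag)) - lkj_log_normalizer(K, shape))


def log_likelihood(observations: Sequence[ScoreChangeObservation],
                   spec: ModelSpec,
                   effects: PerPIEffects,
                   sigma: float) -> float:
    """Gaussian log likelihood sum_n log N(d_n | x_n' beta_{i(n)}, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    total = 0.0
    for obs in observations:
        beta = effects.require(obs.pi_id)
        x = build_design_row(obs, spec)
        if beta.shape != x.shape:
            raise ValueError(
                f"effect vector for PI {obs.pi_id!r} has dimension "
                f"{beta.shape[0]}, design row has {x.shape[0]}")
        resid = obs.d - float(x @ beta)
        total += -0.5 * _LOG_2PI - math.log(sigma) - 0.5 * (resid / sigma) ** 2
    return total


def log_prior(h: Hyperparameters,
              effects: PerPIEffects,
              pc: PriorConfig) -> float:
    """Joint log prior of the hyperparameters and all per-PI effects."""
    p = h.dim
    scales = pc.mu_scales(p)
    lp = float(np.sum(stats.norm.logpdf(h.mu, scale=scales)))
    lp += float(np.sum(half_t_logpdf(h.zeta, pc.zeta_df, pc.zeta_scale)))
    lp += half_normal_logpdf(h.sigma, pc.sigma_scale)
    lp += lkj_cholesky_logpdf(h.omega_chol, pc.lkj_shape)
    if not np.isfinite(lp):
        return -np.inf
    B = h.covariance_chol
    diag = np.diag(B)
    if np.any(diag <= 0):
        # degenerate population covariance: effects density undefined
        raise ValueError("covariance Cholesky has non-positive diagonal; "
                         "cannot evaluate the effects density")
    log_det = float(np.sum(np.log(diag)))
    for beta in effects.beta.values():
        z = np.linalg.solve(B, np.asarray(beta, float) - h.mu)
        lp += -0.5 * p * _LOG_2PI - log_det - 0.5 * float(z @ z)
    return lp
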