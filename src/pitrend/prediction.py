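"""Posterior predictive distributions of future score changes, prediction
intervals, and coverage-probability validation.

The coverage of the nominal 90% interval over held-out assessments is
the model's fail-safe signal: a wound whose observed severity falls
outside its interval is healing atypically and should trigger an actual
expert consultation.

Three predictive modes are supported, differing in where the effect
vector for the predicted lesion comes from:

``population``
    beta = mu draw-by-draw.  This is the "random-effect scales set to
    zero" rule used for the first prediction of a lesion with no history:
    only the population mean trajectory and residual noise enter.
``pi_specific``
    beta ~ MultiNormal(mu, Sigma) draw-by-draw: a new lesion exchangeable
    with the fitted ones; the between-lesion variance widens the interval.
``updating``
    beta conditioned on the lesion's accumulated observed changes (exact
    Gaussian conditional per draw); available in sequential prediction
    once at least one change has been observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .model import ScoreChangeObservation, build_design_row
from .records import build_observations

__all__ = ["PredictionInterval", "CoverageResult", "predictive_distribution",
           "prediction_interval", "coverage_probability",
           "sequential_predict"]

MODES = ("population", "pi_specific", "updating")


@dataclass(frozen=True)
class PredictionInterval:
    """Central posterior predictive interval for a future score change."""

    lower: float
    upper: float
    level: float
    point: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if not self.lower <= self.point <= self.upper:
            raise ValueError("require lower <= point <= upper")

    def covers(self, value: float) -> bool:
        """Closed-interval membership (scores are integers; ties count)."""
        return self.lower <= value <= self.upper

    def shifted(self, offset: float) -> "PredictionInterval":
        return PredictionInterval(self.lower + offset, self.upper + offset,
                                  self.level, self.point + offset)


@dataclass(frozen=True)
class CoverageResult:
    """Per-PI and pooled counts of actual values inside their intervals."""

    per_pi: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for pid, (covered, assessed) in self.per_pi.items():
            if not 0 <= covered <= assessed:
                raise ValueError(f"invalid counts for PI {pid!r}")

    @property
    def pooled(self) -> tuple[int, int]:
        covered = sum(c for c, _ in self.per_pi.values())
        assessed = sum(a for _, a in self.per_pi.values())
        return covered, assessed

    @property
    def pooled_probability(self) -> float:
        covered, assessed = self.pooled
        if assessed == 0:
            raise ValueError("no assessments to pool")
        return covered / assessed

    def per_pi_probability(self) -> dict[str, float]:
        return {pid: c / a for pid, (c, a) in self.per_pi.items() if a}

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]
                    ) -> "CoverageResult":
        return cls(per_pi=dict(counts))


def _effect_draws(samples: PosteriorSamples, mode: str,
                  rng: np.random.Generator,
                  pi_history: Sequence[ScoreChangeObservation] | None = None
                  ) -> np.ndarray:
    """(N, p) effect vector per flattened posterior draw, by mode."""
    mu, zeta, sigma, omega = samples.hyperparameter_draws()
    n, p = mu.shape
    if mode == "population":
        return mu
    if mode == "pi_specific":
        B = zeta[:, :, None] * omega
        z = rng.standard_normal((n, p))
        return mu + np.einsum("nij,nj->ni", B, z)
    if mode == "updating":
        if not pi_history:
            raise ValueError("updating mode needs observed changes")
        X = np.vstack([build_design_row(o, samples.spec)
                       for o in pi_history])
        d = np.array([o.d for o in pi_history])
        B = zeta[:, :, None] * omega
        Sigma = B @ np.swapaxes(B, 1, 2)
        Sigma_inv = np.linalg.inv(Sigma)
        sigma2 = (sigma ** 2)[:, None, None]
        prec = Sigma_inv + (X.T @ X)[None] / sigma2
        cov = np.linalg.inv(prec)
        cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
        rhs = (np.einsum("nij,nj->ni", Sigma_inv, mu)
               + (X.T @ d)[None] / sigma2[:, :, 0])
        mean = np.einsum("nij,nj->ni", cov, rhs)
        chol = np.linalg.cholesky(cov)
        return mean + np.einsum("nij,nj->ni", chol,
                                rng.standard_normal((n, p)))
    raise ValueError(f"unknown predictive mode {mode!r}; expected one of "
                     f"{MODES}")


def predictive_distribution(samples: PosteriorSamples,
                            obs: ScoreChangeObservation,
                            mode: str = "population",
                            seed: int = 0,
                            pi_history: Sequence[ScoreChangeObservation]
                            | None = None) -> np.ndarray:
    """Draws of the future score change d for one covariate configuration.

    For each posterior draw an effect vector is formed per ``mode`` and a
    change is drawn from Normal(x' beta, sigma^2).
    """
    rng = np.random.default_rng(seed)
    x = build_design_row(obs, samples.spec)
    beta = _effect_draws(samples, mode, rng, pi_history)
    _, _, sigma, _ = samples.hyperparameter_draws()
    return beta @ x + sigma * rng.standard_normal(len(sigma))


def prediction_interval(draws: np.ndarray, level: float = 0.90
                        ) -> PredictionInterval:
    """Central interval from empirical predictive quantiles."""
    draws = np.asarray(draws, dtype=float)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if draws.size < 100:
        raise ValueError("need at least 100 predictive draws")
    alpha = (1.0 - level) / 2.0
    lower, point, upper = np.quantile(draws, [alpha, 0.5, 1.0 - alpha])
    return PredictionInterval(float(lower), float(upper), level, float(point))


def coverage_probability(intervals: Sequence[PredictionInterval],
                         actual: Sequence[float],
                         pi_ids: Sequence[str] | None = None
                         ) -> CoverageResult:
    """Fraction of actual values inside their intervals (bounds inclusive).

    ``intervals`` and ``actual`` must align one-to-one; ``pi_ids`` groups
    the counts per lesion (a single pooled group when omitted).
    """
    if len(intervals) != len(actual):
        raise ValueError("intervals and actual values are misaligned: "
                         f"{len(intervals)} vs {len(actual)}")
    if pi_ids is None:
        pi_ids = ["all"] * len(intervals)
    elif len(pi_ids) != len(intervals):
        raise ValueError("pi_ids misaligned with intervals")
    per_pi: dict[str, list[int]] = {}
    for interval, value, pid in zip(intervals, actual, pi_ids):
        counts = per_pi.setdefault(str(pid), [0, 0])
        counts[1] += 1
        if interval.covers(value):
            counts[0] += 1
    return CoverageResult(per_pi={k: (c, a) for k, (c, a) in per_pi.items()})


def sequential_predict(samples: PosteriorSamples,
                       pi_records: pd.DataFrame,
                       level: float = 0.90,
                       mode: str = "population",
                       seed: int = 0) -> pd.DataFrame:
    """Predict each next assessment of one held-out PI from the previous one.

    For assessment j >= 1 the covariates come from assessment j-1 (gap to
    j, elapsed days at j-1, total at the first assessment) and the
    interval for the *total* at j is the interval for the change shifted
    by the total at j-1.  The first prediction always uses the
    population mode (no history exists); later ones use ``mode``, where
    ``updating`` conditions on the changes observed so far.

    Returns one row per predicted assessment: from/to day, interval
    bounds and point on the total-score scale, the actual total, and the
    covered flag.
    """
    if mode not in MODES:
        raise ValueError(f"unknown predictive mode {mode!r}")
    pi_records = pi_records.sort_values("day").reset_index(drop=True)
    if len(pi_records) < 2:
        raise ValueError("need at least 2 assessments to predict")
    days = pi_records["day"].to_numpy()
    if np.any(np.diff(days) <= 0):
        raise ValueError("day indices must strictly increase "
                         "(zero-gap duplicate assessments are invalid)")
    observations = build_observations(pi_records)
    rows = []
    for j, obs in enumerate(observations):
        step_mode = "population" if j == 0 or mode == "population" else mode
        history = observations[:j] if step_mode == "updating" else None
        draws = predictive_distribution(samples, obs, mode=step_mode,
                                        seed=seed + j, pi_history=history)
        interval = prediction_interval(draws, level)
        previous_total = obs.covariates["latest_score"]
        total_interval = interval.shifted(previous_total)
        actual_total = previous_total + obs.d
        rows.append({
            "pi_id": obs.pi_id,
            "from_day": int(obs.duration_day0),
            "to_day": int(obs.duration_day0 + obs.duration_next),
            "lower": total_interval.lower,
            "upper": total_interval.upper,
            "point": total_interval.point,
            "actual": actual_total,
            "covered": total_interval.covers(actual_total),
            "mode": step_mode,
        })
    return pd.DataFrame(rows)
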