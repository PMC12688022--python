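"""Model/Results front end for the score-change analysis.

The workflow mirrors the statsmodels idiom: build a
:class:`ScoreChangeModel` from data, call :meth:`~ScoreChangeModel.fit`
to obtain a :class:`ScoreChangeResults` carrying the posterior draws,
diagnostics and a summary table, and hang prediction, validation and
evidence computations off the results object.

>>> model = ScoreChangeModel.from_dataset(train, spec=ModelSpec.base())
>>> results = model.fit(McmcConfig(seed=1))
>>> results.summary()
>>> results.log_marginal_likelihood().log_ml
>>> results.coverage(test, level=0.90).pooled_probability
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import TrajectoryDataset
from .designr import DEFAULT_CODING, SubscaleCoding
from .evidence import EvidenceEstimate, log_marginal_likelihood
from .inference import (RHAT_THRESHOLD, McmcConfig, PosteriorSamples,
                        sample_posterior)
from .model import (ModelSpec, PriorConfig, ScoreChangeObservation)
from .prediction import (CoverageResult, prediction_interval,
                         predictive_distribution, sequential_predict)
from .records import build_observations, exclude_single_assessment, \
    validate_records

__all__ = ["ScoreChangeModel", "ScoreChangeResults"]


class ScoreChangeModel:
    """Hierarchical Bayesian regression of severity-score changes.

    Parameters
    ----------
    observations:
        The modelled score-change units.
    spec:
        Predictor structure; defaults to the duration-only base model.
    priors:
        Prior scales; defaults match the published analysis.
    """

    def __init__(self, observations: Sequence[ScoreChangeObservation],
                 spec: ModelSpec | None = None,
                 priors: PriorConfig | None = None):
        if not observations:
            raise ValueError("no observations supplied")
        self.observations = list(observations)
        self.spec = spec or ModelSpec.base()
        self.priors = priors or PriorConfig()

    @classmethod
    def from_records(cls, records: pd.DataFrame,
                     spec: ModelSpec | None = None,
                     priors: PriorConfig | None = None,
                     coding: SubscaleCoding = DEFAULT_CODING
                     ) -> "ScoreChangeModel":
        """Build from an assessment-record table (one row per assessment)."""
        validate_records(records, coding)
        records, _ = exclude_single_assessment(records)
        return cls(build_observations(records, coding), spec, priors)

    @classmethod
    def from_dataset(cls, dataset: TrajectoryDataset,
                     spec: ModelSpec | None = None,
                     priors: PriorConfig | None = None) -> "ScoreChangeModel":
        return cls(dataset.observations(), spec, priors)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def pi_ids(self) -> tuple[str, ...]:
        return tuple(sorted({o.pi_id for o in self.observations}))

    def fit(self, mcmc: McmcConfig | None = None,
            sample_effects: bool = True) -> "ScoreChangeResults":
        """Run NUTS and return the results object."""
        samples = sample_posterior(self.observations, self.spec, self.priors,
                                   mcmc, sample_effects=sample_effects)
        return ScoreChangeResults(self, samples)


@dataclass
class ScoreChangeResults:
    """Posterior of a fitted score-change model."""

    model: ScoreChangeModel
    samples: PosteriorSamples

    # -- summaries ---------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 90% interval and R-hat per
        hyperparameter."""
        return self.samples.summary()

    def rhat(self, include_effects: bool = True) -> pd.Series:
        return self.samples.rhat(include_effects=include_effects)

    @property
    def max_rhat(self) -> float:
        return self.samples.max_rhat()

    @property
    def converged(self) -> bool:
        """Convergence gate: every split R-hat below 1.1."""
        return self.samples.converged(RHAT_THRESHOLD)

    @property
    def divergences(self) -> int:
        return self.samples.divergences

    # -- evidence ----------------------------------------------------------
    def log_marginal_likelihood(self, n_repetitions: int = 5,
                                seed: int = 0) -> EvidenceEstimate:
        """Warp-III bridge-sampling evidence (mean over repetitions)."""
        return log_marginal_likelihood(self.samples,
                                       n_repetitions=n_repetitions, seed=seed)

    # -- prediction --------------------------------------------------------
    def predictive_distribution(self, obs: ScoreChangeObservation,
                                mode: str = "population",
                                seed: int = 0) -> np.ndarray:
        return predictive_distribution(self.samples, obs, mode=mode,
                                       seed=seed)

    def prediction_interval(self, obs: ScoreChangeObservation,
                            level: float = 0.90, mode: str = "population",
                            seed: int = 0):
        draws = self.predictive_distribution(obs, mode=mode, seed=seed)
        return prediction_interval(draws, level)

    def sequential_predict(self, pi_records: pd.DataFrame,
                           level: float = 0.90, mode: str = "population",
                           seed: int = 0) -> pd.DataFrame:
        return sequential_predict(self.samples, pi_records, level=level,
                                  mode=mode, seed=seed)

    def prediction_report(self, test: TrajectoryDataset,
                          level: float = 0.90, mode: str = "population",
                          seed: int = 0) -> pd.DataFrame:
        """Sequential predictions for every held-out PI, one row per
        predicted assessment."""
        frames = [self.sequential_predict(test.pi_records(pid), level=level,
                                          mode=mode, seed=seed + 101 * k)
                  for k, pid in enumerate(test.pi_ids)]
        return pd.concat(frames, ignore_index=True)

    def coverage(self, test: TrajectoryDataset, level: float = 0.90,
                 mode: str = "population", seed: int = 0) -> CoverageResult:
        """Coverage of the level-``level`` intervals over a held-out set:
        the fail-safe statistic."""
        report = self.prediction_report(test, level=level, mode=mode,
                                        seed=seed)
        per_pi = {
            str(pid): (int(grp["covered"].sum()), int(len(grp)))
            for pid, grp in report.groupby("pi_id")
        }
        return CoverageResult(per_pi=per_pi)
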