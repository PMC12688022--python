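"""Predictor selection by posterior model probabilities and marginal
likelihood, mirroring the staged procedure the model was developed with.

Stage 1 (screening): starting from the duration-only base model M0, each
candidate predictor p defines a one-addition model M_p.  Under equal
prior model probabilities, P(M_p | data) = Z_p / (Z_p + Z_0) with Z the
marginal likelihoods; predictors with probability strictly above 0.95
are selected.

Stage 2 (combination): every non-empty subset of the selected predictors
(each on top of the base model) is fitted, and the subset with the
highest log marginal likelihood becomes the candidate.

Stage 3 (cross-fold vote): stages 1-2 run on several random 80% subsets
of training PIs; each fold nominates a candidate, all distinct
candidates are re-scored on the full training data, and the highest
log marginal likelihood wins.  Ties within the evidence estimator's
repetition SD go to the smaller model, then lexicographically.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evidence import (EvidenceEstimate, log_marginal_likelihood,
                       posterior_model_probability)
from .inference import (RHAT_THRESHOLD, McmcConfig, PosteriorSamples,
                        sample_posterior)
from .model import (DURATION_NEXT_SQ, ModelSpec, PriorConfig,
                    ScoreChangeObservation)

__all__ = ["ScreenResult", "CombinationResult", "SelectionReport",
           "DEFAULT_CANDIDATES", "screen_predictors", "best_combination",
           "select_final"]

logger = logging.getLogger(__name__)

#: the full candidate list of the selection procedure: the quadratic gap
#: term, elapsed-time terms, severity summaries, subscale dummies, risk
#: factors, comorbidities and age
DEFAULT_CANDIDATES: tuple[str, ...] = (
    DURATION_NEXT_SQ, "duration_day0", "duration_day0_sq",
    "baseline_score", "latest_score", "age",
    "e_large", "e_small", "s_large", "s_small", "i_large", "i_small",
    "g_large", "g_small", "n_large", "n_small", "p_large", "p_small",
    "posture_bed", "posture_chair", "bony_prominence", "joint_contracture",
    "malnutrition", "wet_skin", "edema", "skin_tear",
    "dementia", "diabetes", "liver_disease", "cardiovascular_disease",
    "cerebrovascular_disease", "respiratory_disease", "cancer",
)


def _spec_dict(spec: ModelSpec) -> dict:
    return {"predictors": list(spec.predictors),
            "include_quadratic_duration": spec.include_quadratic_duration}


@dataclass(frozen=True)
class ScreenResult:
    """Per-predictor posterior probabilities vs the base model."""

    probabilities: dict[str, float]
    selected: tuple[str, ...]
    failed: tuple[str, ...]
    base_log_ml: float

    def to_dict(self) -> dict:
        return {"probabilities": self.probabilities,
                "selected": list(self.selected),
                "failed": list(self.failed),
                "base_log_ml": self.base_log_ml}


@dataclass(frozen=True)
class CombinationResult:
    spec: ModelSpec
    log_ml: float
    table: tuple[tuple[str, float, float], ...]   # (label, log_ml, sd)

    def to_dict(self) -> dict:
        return {"spec": _spec_dict(self.spec), "log_ml": self.log_ml,
                "table": [list(row) for row in self.table]}


@dataclass(frozen=True)
class SelectionReport:
    """Full record of the staged selection procedure."""

    fold_screens: tuple[ScreenResult, ...]
    fold_candidates: tuple[tuple[ModelSpec, float], ...]
    candidate_log_ml: tuple[tuple[ModelSpec, float, float], ...]
    final: ModelSpec
    final_log_ml: float

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "fold_screens": [s.to_dict() for s in self.fold_screens],
            "fold_candidates": [
                {"spec": _spec_dict(spec), "log_ml": lml}
                for spec, lml in self.fold_candidates],
            "candidate_log_ml": [
                {"spec": _spec_dict(spec), "log_ml": lml, "sd": sd}
                for spec, lml, sd in self.candidate_log_ml],
            "final": _spec_dict(self.final),
            "final_log_ml": self.final_log_ml,
        }, indent=indent)


def _fit_and_evidence(observations, spec, priors, mcmc, n_repetitions,
                      seed) -> tuple[PosteriorSamples, EvidenceEstimate]:
    samples = sample_posterior(observations, spec, priors,
                               McmcConfig(n_chains=mcmc.n_chains,
                                          n_warmup=mcmc.n_warmup,
                                          n_draws=mcmc.n_draws,
                                          seed=seed,
                                          target_accept=mcmc.target_accept,
                                          max_tree_depth=mcmc.max_tree_depth),
                               sample_effects=False)
    max_rhat = samples.max_rhat(include_effects=False)
    if max_rhat >= RHAT_THRESHOLD:
        raise _ConvergenceFailure(spec, max_rhat)
    evidence = log_marginal_likelihood(samples, n_repetitions=n_repetitions,
                                       seed=seed)
    return samples, evidence


class _ConvergenceFailure(RuntimeError):
    def __init__(self, spec: ModelSpec, max_rhat: float):
        super().__init__(f"model {spec.label()!r} failed the R-hat gate "
                         f"(max {max_rhat:.3f} >= {RHAT_THRESHOLD})")
        self.spec = spec
        self.max_rhat = max_rhat


def screen_predictors(observations: Sequence[ScoreChangeObservation],
                      candidates: Sequence[str] = DEFAULT_CANDIDATES,
                      priors: PriorConfig | None = None,
                      mcmc: McmcConfig | None = None,
                      n_repetitions: int = 5,
                      threshold: float = 0.95,
                      seed: int = 0,
                      base: ModelSpec | None = None) -> ScreenResult:
    """Single-addition screen: select candidates whose posterior model
    probability against the duration-only base strictly exceeds the
    threshold.  Models failing the convergence gate are excluded and
    reported in ``failed``.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    base = base or ModelSpec.base()
    _, base_ev = _fit_and_evidence(observations, base, priors, mcmc,
                                   n_repetitions, seed)
    probabilities: dict[str, float] = {}
    failed: list[str] = []
    for k, name in enumerate(candidates):
        spec = base.with_predictor(name)
        try:
            _, ev = _fit_and_evidence(observations, spec, priors, mcmc,
                                      n_repetitions, seed + 1000 + k)
        except _ConvergenceFailure as exc:
            logger.warning("screen: %s", exc)
            failed.append(name)
            continue
        probabilities[name] = posterior_model_probability(
            ev.log_ml, base_ev.log_ml)
    selected = tuple(name for name in candidates
                     if probabilities.get(name, 0.0) > threshold)
    return ScreenResult(probabilities=probabilities, selected=selected,
                        failed=tuple(failed), base_log_ml=base_ev.log_ml)


def _tie_break(entries: list[tuple[ModelSpec, float, float]]
               ) -> tuple[ModelSpec, float]:
    """Highest evidence wins; entries within the winner's estimator SD are
    ties resolved toward fewer predictors, then lexicographic label."""
    best_lml = max(lml for _, lml, _ in entries)
    best_sd = max(sd for _, lml, sd in entries if lml == best_lml)
    tied = [(spec, lml) for spec, lml, sd in entries
            if lml >= best_lml - (best_sd if np.isfinite(best_sd) else 0.0)]
    tied.sort(key=lambda item: (-item[1],))
    winner = min(tied, key=lambda item: (item[0].dim, item[0].label()))
    return winner


def best_combination(observations: Sequence[ScoreChangeObservation],
                     selected: Sequence[str],
                     priors: PriorConfig | None = None,
                     mcmc: McmcConfig | None = None,
                     n_repetitions: int = 5,
                     seed: int = 0,
                     base: ModelSpec | None = None,
                     max_models: int = 64) -> CombinationResult:
    """Exhaustive search over non-empty subsets of the selected predictors."""
    if not selected:
        raise ValueError("no predictors selected; combination search is "
                         "undefined (fall back to the base model)")
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    base = base or ModelSpec.base()
    n_models = 2 ** len(selected) - 1
    if n_models > max_models:
        raise ValueError(
            f"combination search over {len(selected)} predictors would fit "
            f"{n_models} models, exceeding the budget of {max_models}")
    entries = []
    table = []
    counter = 0
    for size in range(1, len(selected) + 1):
        for subset in itertools.combinations(selected, size):
            spec = base
            for name in subset:
                spec = spec.with_predictor(name)
            _, ev = _fit_and_evidence(observations, spec, priors, mcmc,
                                      n_repetitions, seed + 2000 + counter)
            counter += 1
            entries.append((spec, ev.log_ml, ev.sd))
            table.append((spec.label(), ev.log_ml, ev.sd))
    winner, winner_lml = _tie_break(entries)
    return CombinationResult(spec=winner, log_ml=winner_lml,
                             table=tuple(table))


def select_final(observations: Sequence[ScoreChangeObservation],
                 candidates: Sequence[str] = DEFAULT_CANDIDATES,
                 n_folds: int = 5,
                 fold_fraction: float = 0.8,
                 priors: PriorConfig | None = None,
                 mcmc: McmcConfig | None = None,
                 n_repetitions: int = 5,
                 threshold: float = 0.95,
                 seed: int = 0,
                 max_models: int = 64) -> SelectionReport:
    """The staged selection: per-fold screen+combine, then an all-data
    evidence comparison of the fold candidates.

    Folds are PI-level random subsets (``fold_fraction`` of lesions,
    drawn without replacement, seeded); a fold whose screen selects
    nothing nominates the base model.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    pi_ids = sorted({o.pi_id for o in observations})
    n_fold_pis = int(round(len(pi_ids) * fold_fraction))
    if n_fold_pis < 2 or len(pi_ids) < n_folds:
        raise ValueError("too few PIs for the fold procedure")
    rng = np.random.default_rng(seed)
    fold_screens: list[ScreenResult] = []
    fold_candidates: list[tuple[ModelSpec, float]] = []
    for fold in range(n_folds):
        chosen = set(rng.choice(pi_ids, size=n_fold_pis, replace=False))
        fold_obs = [o for o in observations if o.pi_id in chosen]
        screen = screen_predictors(fold_obs, candidates, priors, mcmc,
                                   n_repetitions, threshold,
                                   seed=seed + 10_000 * (fold + 1))
        fold_screens.append(screen)
        if not screen.selected:
            logger.warning("fold %d: empty selection, falling back to the "
                           "base model", fold)
            fold_candidates.append((ModelSpec.base(), screen.base_log_ml))
            continue
        combo = best_combination(fold_obs, screen.selected, priors, mcmc,
                                 n_repetitions,
                                 seed=seed + 10_000 * (fold + 1) + 5000,
                                 max_models=max_models)
        fold_candidates.append((combo.spec, combo.log_ml))

    unique: dict[str, ModelSpec] = {}
    for spec, _ in fold_candidates:
        unique.setdefault(spec.label(), spec)
    if not unique:
        raise ValueError("no fold produced a candidate model")
    entries = []
    for k, (label, spec) in enumerate(sorted(unique.items())):
        _, ev = _fit_and_evidence(observations, spec, priors, mcmc,
                                  n_repetitions, seed + 77_000 + k)
        entries.append((spec, ev.log_ml, ev.sd))
    final, final_lml = _tie_break(entries)
    best_lml = max(lml for _, lml, _ in entries)
    best_sd = max(sd for _, lml, sd in entries if lml == best_lml)
    tolerance = best_sd if np.isfinite(best_sd) else 0.0
    assert final_lml >= best_lml - tolerance, \
        "final model must carry the highest all-data evidence up to the " \
        "estimator SD tie band"
    return SelectionReport(
        fold_screens=tuple(fold_screens),
        fold_candidates=tuple(fold_candidates),
        candidate_log_ml=tuple(entries),
        final=final, final_log_ml=final_lml)
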