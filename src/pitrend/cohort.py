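"""Synthetic longitudinal cohorts of pressure-injury trajectories.

The generator emulates the structure of the home-care consultation
cohort the model targets: a small number of hard-to-heal PIs in older
patients, assessed repeatedly a couple of weeks apart, with total
DESIGN-R 2020 scores evolving according to the hierarchical score-change
model itself.  Default marginals (cohort size, follow-up, age, risk and
comorbidity prevalences) match the published training-cohort
characteristics; the default generating hyperparameters are the
published posterior means of the best model, with a residual SD of 2
score points.

Each PI is treated as an independent unit — the model indexes lesions,
not patients — and every simulated trajectory carries its generating
truth in the dataset's provenance so that recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .designr import (DEFAULT_CODING, SUBSCALE_LETTERS, SubscaleCoding,
                      binarize_subscale)
from .model import (Hyperparameters, ModelSpec, ScoreChangeObservation,
                    build_design_row)
from .records import build_observations, validate_records

__all__ = ["CohortConfig", "TrajectoryDataset", "study_truth",
           "make_truth", "generate_cohort", "split_train_test",
           "decompose_total"]

#: training-cohort prevalences of the binary covariates
STUDY_PREVALENCES: Mapping[str, float] = {
    "posture_bed": 0.64, "posture_chair": 0.64, "bony_prominence": 0.43,
    "joint_contracture": 0.36, "malnutrition": 0.57, "wet_skin": 0.43,
    "edema": 0.29, "skin_tear": 0.43,
    "dementia": 0.36, "diabetes": 0.21, "liver_disease": 0.14,
    "cardiovascular_disease": 0.14, "cerebrovascular_disease": 0.36,
    "respiratory_disease": 0.14, "cancer": 0.14,
}

#: population-mean and between-PI-scale defaults per design column,
#: taken from the best model's published posterior summary
_TRUTH_MU = {"intercept": 3.91, "duration_next": -0.55,
             "duration_next_sq": 0.02, "duration_day0": -0.52,
             "duration_day0_sq": 0.02, "baseline_score": -0.10, "age": 0.05}
_TRUTH_ZETA = {"intercept": 0.97, "duration_next": 0.17,
               "duration_next_sq": 0.01, "duration_day0": 0.26,
               "duration_day0_sq": 0.01, "baseline_score": 0.13, "age": 0.04}
_TRUTH_SIGMA = 2.0


def make_truth(spec: ModelSpec,
               mu: Mapping[str, float] | None = None,
               zeta: Mapping[str, float] | None = None,
               sigma: float = _TRUTH_SIGMA,
               omega_chol: np.ndarray | None = None) -> Hyperparameters:
    """Generating hyperparameters for ``spec``, defaulting per column to the
    study-based values (unlisted columns get mu 0, zeta 0.1)."""
    mu = {**_TRUTH_MU, **(mu or {})}
    zeta = {**_TRUTH_ZETA, **(zeta or {})}
    cols = spec.column_names
    return Hyperparameters(
        mu=np.array([mu.get(c, 0.0) for c in cols]),
        zeta=np.array([zeta.get(c, 0.1) for c in cols]),
        omega_chol=np.eye(len(cols)) if omega_chol is None else omega_chol,
        sigma=sigma)


def study_truth() -> tuple[ModelSpec, Hyperparameters]:
    """The best-model predictor structure with its study-based truth."""
    spec = ModelSpec.published_best_structure()
    return spec, make_truth(spec)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the eligible cohort: 18 PIs (the 80:20 split then
    yields 14 training and 4 test lesions), 2-6 assessments per PI about
    two weeks apart, ages ~79 (8), moderate baseline severity, and the
    published covariate prevalences.
    """

    n_pis: int = 18
    assessments_per_pi: tuple[int, int] = (2, 6)
    spacing_mean_days: float = 14.7
    spacing_sd_days: float = 6.0
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_PREVALENCES))
    age_mean: float = 79.4
    age_sd: float = 8.4
    baseline_mean: float = 15.0
    baseline_sd: float = 6.0
    spec: ModelSpec = field(default_factory=ModelSpec.published_best_structure)
    truth: Hyperparameters | None = None
    integer_scores: bool = True
    clip_scores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pis < 1:
            raise ValueError("n_pis must be >= 1")
        if self.spacing_mean_days <= 0 or self.spacing_sd_days < 0:
            raise ValueError("assessment spacing must be positive")
        lo, hi = self.assessments_per_pi
        if lo < 2 or hi < lo:
            raise ValueError("assessments_per_pi must satisfy 2 <= lo <= hi")
        for name, prob in self.covariate_prevalences.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")

    def resolved_truth(self) -> Hyperparameters:
        return self.truth if self.truth is not None else make_truth(self.spec)


@dataclass
class TrajectoryDataset:
    """Longitudinal assessment records plus generation provenance."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    truth: Hyperparameters | None = None
    truth_spec: ModelSpec | None = None

    @property
    def pi_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.records["pi_id"].unique()))

    @property
    def n_pis(self) -> int:
        return len(self.pi_ids)

    def follow_up_days(self) -> pd.Series:
        return self.records.groupby("pi_id")["day"].max().sort_index()

    def observations(self, coding: SubscaleCoding = DEFAULT_CODING
                     ) -> list[ScoreChangeObservation]:
        return build_observations(self.records, coding)

    def pi_records(self, pi_id: str) -> pd.DataFrame:
        out = self.records[self.records["pi_id"] == pi_id]
        return out.sort_values("day").reset_index(drop=True)

    def subset(self, pi_ids) -> "TrajectoryDataset":
        keep = self.records["pi_id"].isin(list(pi_ids))
        return TrajectoryDataset(
            records=self.records[keep].reset_index(drop=True),
            provenance={**self.provenance, "subset": sorted(map(str, pi_ids))},
            truth=self.truth, truth_spec=self.truth_spec)


def decompose_total(total: int, coding: SubscaleCoding = DEFAULT_CODING,
                    weights: Mapping[str, float] | None = None) -> dict[str, int]:
    """Split an integer total into permissible subscale values summing to
    it exactly.

    Allocation is proportional (by default to each subscale's maximum),
    snapped down to permissible values for pocket, size, inflammation and
    necrotic tissue; the remainder (guaranteed <= 12) is covered exactly
    by the fine-grained granulation and exudate scales.
    """
    total = int(total)
    maxima = {s: max(coding.permissible[s]) for s in coding.permissible}
    if not 0 <= total <= sum(maxima.values()):
        raise ValueError(f"total {total} outside the representable range")
    weights = weights or {s: maxima[s] / sum(maxima.values())
                          for s in maxima}
    coarse = ("pocket", "size", "inflammation_infection", "necrotic")
    values = {s: 0 for s in coding.permissible}
    for sub in coarse:
        target = total * weights.get(sub, 0.0)
        values[sub] = max(v for v in coding.permissible[sub] if v <= target)
    remaining = total - sum(values.values())
    while remaining > 12:
        steps = []
        for sub in coarse:
            larger = [v for v in coding.permissible[sub] if v > values[sub]]
            if larger:
                steps.append((min(larger) - values[sub], sub))
        step, sub = min(steps)
        values[sub] += step
        remaining -= step
    ge_table = {0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (3, 0), 4: (4, 0),
                5: (4, 1), 6: (6, 0), 7: (6, 1), 8: (5, 3), 9: (6, 3),
                10: (4, 6), 11: (5, 6), 12: (6, 6)}
    g_val, e_val = ge_table[remaining]
    values["granulation"], values["exudate"] = g_val, e_val
    assert sum(values.values()) == total
    return values


def generate_cohort(config: CohortConfig) -> TrajectoryDataset:
    """Simulate one cohort from the hierarchical model.

    Per-PI effect vectors are drawn from MultiNormal(mu, Sigma), then
    successive score changes from the Gaussian likelihood; integer mode
    rounds totals, clips them into the representable range (clipping
    events are counted in the provenance) and decomposes each total into
    permissible subscale values summing to it exactly.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.resolved_truth()
    spec = config.spec
    if truth.dim != spec.dim:
        raise ValueError("truth dimension does not match the model spec")
    B = truth.covariance_chol
    coding = DEFAULT_CODING
    max_total = coding.max_total
    lo, hi = config.assessments_per_pi
    rows = []
    n_clipped = 0
    width = max(3, len(str(config.n_pis)))
    for i in range(config.n_pis):
        pid = f"PI{i:0{width}d}"
        age = float(rng.normal(config.age_mean, config.age_sd))
        flags = {name: int(rng.uniform() < prob)
                 for name, prob in config.covariate_prevalences.items()}
        n_assess = int(rng.integers(lo, hi + 1))
        gaps = np.maximum(
            1, np.round(rng.normal(config.spacing_mean_days,
                                   config.spacing_sd_days,
                                   n_assess - 1))).astype(int)
        days = np.concatenate([[0], np.cumsum(gaps)])
        beta = truth.mu + B @ rng.standard_normal(truth.dim)

        y0 = float(np.clip(rng.normal(config.baseline_mean,
                                      config.baseline_sd), 1.0, max_total))
        if config.integer_scores:
            y0 = float(int(round(y0)))
        totals = [y0]
        for j in range(n_assess - 1):
            obs = ScoreChangeObservation(
                pi_id=pid, duration_day0=float(days[j]),
                duration_next=float(days[j + 1] - days[j]), d=0.0,
                covariates=_covariates_for(totals, age, flags, coding))
            x = build_design_row(obs, spec)
            d = float(x @ beta + truth.sigma * rng.standard_normal())
            y_next = totals[-1] + d
            if config.clip_scores:
                clipped = np.clip(y_next, 0.0, max_total)
                if clipped != y_next:
                    n_clipped += 1
                y_next = float(clipped)
            if config.integer_scores:
                y_next = float(int(round(np.clip(y_next, 0.0, max_total))))
            totals.append(y_next)
        for j, (day, total) in enumerate(zip(days, totals)):
            sub_values = decompose_total(
                int(round(np.clip(total, 0, max_total))), coding)
            row = {"pi_id": pid, "day": int(day), "age": round(age, 1),
                   "total": total, **flags}
            for sub, letter in SUBSCALE_LETTERS.items():
                row[letter] = sub_values[sub]
            rows.append(row)
    df = pd.DataFrame(rows)
    if config.integer_scores:
        df["total"] = df["total"].astype(int)
        # integer totals are definitionally the subscale sums
        assert (df["total"] == df[["e", "s", "i", "g", "n", "p"]]
                .sum(axis=1)).all()
    validate_records(df.drop(columns=["total"]), coding)
    provenance = {
        "config": _config_provenance(config),
        "seed": config.seed,
        "n_clipped": n_clipped,
        "truth": {
            "mu": truth.mu.tolist(), "zeta": truth.zeta.tolist(),
            "omega_chol": truth.omega_chol.tolist(), "sigma": truth.sigma,
        },
    }
    return TrajectoryDataset(records=df, provenance=provenance,
                             truth=truth, truth_spec=spec)


def _covariates_for(totals: list[float], age: float, flags: dict,
                    coding: SubscaleCoding) -> dict[str, float]:
    latest = totals[-1]
    cov = {"baseline_score": float(totals[0]), "latest_score": float(latest),
           "age": age, **{k: float(v) for k, v in flags.items()}}
    sub_values = decompose_total(
        int(round(np.clip(latest, 0, coding.max_total))), coding)
    for sub, letter in SUBSCALE_LETTERS.items():
        dummies = binarize_subscale(sub, sub_values[sub], coding)
        cov[f"{letter}_large"] = float(dummies.large)
        cov[f"{letter}_small"] = float(dummies.small)
    return cov


def _config_provenance(config: CohortConfig) -> dict:
    out = {
        "n_pis": config.n_pis,
        "assessments_per_pi": list(config.assessments_per_pi),
        "spacing_mean_days": config.spacing_mean_days,
        "spacing_sd_days": config.spacing_sd_days,
        "age_mean": config.age_mean, "age_sd": config.age_sd,
        "baseline_mean": config.baseline_mean,
        "baseline_sd": config.baseline_sd,
        "covariate_prevalences": dict(config.covariate_prevalences),
        "integer_scores": config.integer_scores,
        "spec": {"predictors": list(config.spec.predictors),
                 "include_quadratic_duration":
                     config.spec.include_quadratic_duration},
    }
    return out


def split_train_test(data: TrajectoryDataset, test_fraction: float = 0.2
                     ) -> tuple[TrajectoryDataset, TrajectoryDataset]:
    """PI-level split holding out the longest-followed lesions as test.

    The ``test_fraction`` of PIs with the longest follow-up form the test
    set (time-robustness evaluation); ties break lexicographically by PI
    identifier so the split is reproducible.  Records of one PI are never
    divided between the sets.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if data.n_pis < 2:
        raise ValueError("need at least 2 PIs to split")
    n_test = int(np.floor(data.n_pis * test_fraction + 0.5))
    if n_test < 1:
        raise ValueError(
            f"test_fraction {test_fraction} selects no PI out of "
            f"{data.n_pis}")
    if n_test >= data.n_pis:
        raise ValueError("test_fraction selects every PI")
    follow_up = data.follow_up_days()
    order = sorted(follow_up.index, key=lambda pid: (-follow_up[pid], pid))
    test_ids = sorted(order[:n_test])
    train_ids = sorted(order[n_test:])
    return data.subset(train_ids), data.subset(test_ids)
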