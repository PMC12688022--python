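"""Quantitative evaluation statistics for expert review of care
recommendations on clinical vignettes.

An expert rates a recommendation set per care field and vignette on a
five-point scale: 0 — both the base and the expertise-enriched algorithm
perfectly match the expert's judgment; 1 — worse than base; 2 — as bad
as base; 3 — better than base; 4 — better than base and a perfect match.

Two summary proportions follow.  The *agreement proportion* counts
ratings in {0, 3, 4} (the enriched recommendation is judged appropriate)
over all ratings.  The *improvement proportion* counts ratings in
{3, 4} over ratings in {1, 2, 3, 4}; when every rating of a field is 0
there is nothing to improve on and the field's value is NULL, excluded
from pooling numerator and denominator alike.  Expected healing is
rated once per vignette on 1 (worsens) to 4 (much improves) and
summarized by its mean.

The nine care fields are fixed: pressure relief, nutritional
management, shear relief, moisture management, wound dressing use, care
for physical factors, care for systemic disorder, selection of wound
dressings/ointments/negative-pressure therapy, and wound cleansing.

The packaged data files carry the published per-field counts; the
per-vignette rating files are synthetic reconstructions consistent with
those counts (the individual ratings are unpublished), suitable for
exercising the rating-level code paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["FIELDS", "Proportion", "agreement_proportion",
           "improvement_proportion", "expected_healing_mean",
           "pool_proportions", "load_field_counts",
           "load_synthetic_ratings", "load_synthetic_healing",
           "metrics_from_ratings", "metrics_report"]

FIELDS = (
    "pressure_relief", "nutritional_management", "shear_relief",
    "moisture_management", "wound_dressing_use", "physical_factor",
    "systemic_disorder", "dressing_selection", "wound_cleansing",
)

_AGREE_SET = {0, 3, 4}
_IMPROVE_NUM = {3, 4}
_IMPROVE_DEN = {1, 2, 3, 4}


@dataclass(frozen=True)
class Proportion:
    """A count-based fraction that keeps its numerator and denominator."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")
        if self.denominator == 0:
            raise ValueError("denominator must be positive")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.value:.2f} ({self.numerator}/{self.denominator})"


def _check_scale(ratings: Sequence[int], allowed: set, what: str) -> list[int]:
    values = [int(r) for r in ratings]
    if not values:
        raise ValueError(f"no {what} ratings supplied")
    for r in values:
        if r not in allowed:
            raise ValueError(f"{what} rating {r} outside the scale "
                             f"{sorted(allowed)}")
    return values


def agreement_proportion(ratings: Sequence[int]) -> Proportion:
    """Fraction of ratings in {0, 3, 4} among all ratings."""
    values = _check_scale(ratings, {0, 1, 2, 3, 4}, "vignette")
    return Proportion(sum(r in _AGREE_SET for r in values), len(values))


def improvement_proportion(ratings: Sequence[int]) -> Proportion | None:
    """Fraction of ratings in {3, 4} among those in {1, 2, 3, 4}; NULL
    (None) when every rating is 0."""
    values = _check_scale(ratings, {0, 1, 2, 3, 4}, "vignette")
    denominator = sum(r in _IMPROVE_DEN for r in values)
    if denominator == 0:
        return None
    return Proportion(sum(r in _IMPROVE_NUM for r in values), denominator)


def expected_healing_mean(ratings: Sequence[int]) -> float:
    """Mean of per-vignette expected-healing ratings on the 1-4 scale."""
    values = _check_scale(ratings, {1, 2, 3, 4}, "healing")
    return sum(values) / len(values)


def pool_proportions(parts: Iterable[Proportion | None]) -> Proportion:
    """Count-wise pooling: sum of numerators over sum of denominators.

    NULL fields contribute neither; pooling is count-wise rather than a
    mean of per-field fractions.
    """
    num = den = 0
    for part in parts:
        if part is None:
            continue
        num += part.numerator
        den += part.denominator
    if den == 0:
        raise ValueError("nothing to pool: every field is NULL")
    return Proportion(num, den)


# ---------------------------------------------------------------------------
# packaged fixtures

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("pitrend.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_field_counts() -> pd.DataFrame:
    """Published per-field agreement/improvement counts for all 3 rounds."""
    return _read_packaged("study1_field_counts.csv")


def load_synthetic_ratings() -> pd.DataFrame:
    """Synthetic per-vignette ratings consistent with the published counts."""
    return _read_packaged("study1_ratings_synthetic.csv")


def load_synthetic_healing() -> pd.DataFrame:
    """Synthetic expected-healing ratings matching the published round means."""
    return _read_packaged("study1_healing_synthetic.csv")


# ---------------------------------------------------------------------------
# reports

def metrics_from_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-field and pooled metrics from a (round, field, vignette, score)
    rating table; one output row per round and field plus a pooled row."""
    rows = []
    for rnd, per_round in ratings.groupby("round"):
        agreements, improvements = [], []
        for fld in FIELDS:
            scores = per_round.loc[per_round["field"] == fld, "score"]
            if scores.empty:
                continue
            agree = agreement_proportion(scores.tolist())
            improve = improvement_proportion(scores.tolist())
            agreements.append(agree)
            improvements.append(improve)
            rows.append({"round": rnd, "field": fld,
                         "agreement": agree.value,
                         "agree_num": agree.numerator,
                         "agree_den": agree.denominator,
                         "improvement": None if improve is None
                         else improve.value,
                         "improve_num": None if improve is None
                         else improve.numerator,
                         "improve_den": None if improve is None
                         else improve.denominator})
        pooled_a = pool_proportions(agreements)
        pooled_i = pool_proportions(improvements)
        rows.append({"round": rnd, "field": "total",
                     "agreement": pooled_a.value,
                     "agree_num": pooled_a.numerator,
                     "agree_den": pooled_a.denominator,
                     "improvement": pooled_i.value,
                     "improve_num": pooled_i.numerator,
                     "improve_den": pooled_i.denominator})
    return pd.DataFrame(rows)


def metrics_report(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pooled agreement and improvement per round from per-field counts
    (the packaged published counts by default)."""
    counts = load_field_counts() if counts is None else counts
    rows = []
    for rnd, per_round in counts.groupby("round"):
        agree = pool_proportions(
            Proportion(int(r.agree_num), int(r.agree_den))
            for r in per_round.itertuples())
        improve = pool_proportions(
            None if pd.isna(r.improve_den)
            else Proportion(int(r.improve_num), int(r.improve_den))
            for r in per_round.itertuples())
        rows.append({"round": rnd,
                     "agreement": agree.value,
                     "agree_counts": f"{agree.numerator}/{agree.denominator}",
                     "improvement": improve.value,
                     "improve_counts":
                         f"{improve.numerator}/{improve.denominator}"})
    return pd.DataFrame(rows)
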