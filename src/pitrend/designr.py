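"""DESIGN-R 2020 pressure-injury severity scoring.

DESIGN-R 2020 rates a pressure injury on seven subscales: Depth (D),
Exudate (E), Size (S), Inflammation/infection (I), Granulation (G),
Necrotic tissue (N) and Pocket (P).  The total severity score is the sum
of the six non-depth subscales; depth is recorded but never enters the
total.  Each subscale's permissible point values are split by the
instrument into a severe ("large", uppercase letter) and a mild
("small", lowercase letter) category; score 0 belongs to neither.

The exudate rule is the canonical example: E=6 is "large" E, E=1 or 3 is
"small" e, and E=0 sets both indicators to 0.  The partitions for the
remaining subscales shipped here follow the published DESIGN-R 2020
uppercase/lowercase convention and can be overridden via
:class:`SubscaleCoding` when a local variant is in use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SUBSCALES",
    "SubscaleCoding",
    "DEFAULT_CODING",
    "DesignRAssessment",
    "SubscaleDummies",
    "total_score",
    "binarize_subscale",
    "score_change",
]

#: the six subscales that enter the total, in conventional order
SUBSCALES = ("exudate", "size", "inflammation_infection", "granulation",
             "necrotic", "pocket")

#: short column letters used in CSV files
SUBSCALE_LETTERS = {
    "exudate": "e",
    "size": "s",
    "inflammation_infection": "i",
    "granulation": "g",
    "necrotic": "n",
    "pocket": "p",
}


class MissingSubscaleError(ValueError):
    """A required subscale score is absent."""


class SubscaleValueError(ValueError):
    """A subscale score is outside the instrument's permissible value set."""


@dataclass(frozen=True)
class SubscaleCoding:
    """Permissible value sets and the large/small partition per subscale.

    ``large[sub] | small[sub] | {0}`` must equal ``permissible[sub]`` and the
    three parts must be disjoint.  Defaults are derived from the DESIGN-R
    2020 instrument (uppercase = severe = "large", lowercase = mild =
    "small"); they are instrument conventions, overridable per deployment.
    """

    permissible: Mapping[str, frozenset] = field(default_factory=lambda: {
        "exudate": frozenset({0, 1, 3, 6}),
        "size": frozenset({0, 3, 6, 8, 9, 12, 15}),
        "inflammation_infection": frozenset({0, 1, 3, 9}),
        "granulation": frozenset({0, 1, 3, 4, 5, 6}),
        "necrotic": frozenset({0, 3, 6}),
        "pocket": frozenset({0, 6, 9, 12, 24}),
    })
    large: Mapping[str, frozenset] = field(default_factory=lambda: {
        "exudate": frozenset({6}),
        "size": frozenset({15}),
        "inflammation_infection": frozenset({3, 9}),
        "granulation": frozenset({4, 5, 6}),
        "necrotic": frozenset({3, 6}),
        "pocket": frozenset({6, 9, 12, 24}),
    })

    def __post_init__(self) -> None:
        for sub in SUBSCALES:
            perm = self.permissible[sub]
            big = self.large[sub]
            if 0 not in perm:
                raise ValueError(f"{sub}: permissible set must contain 0")
            if not big <= perm or 0 in big:
                raise ValueError(f"{sub}: large set must be a subset of the "
                                 "non-zero permissible values")

    def small(self, sub: str) -> frozenset:
        return self.permissible[sub] - self.large[sub] - {0}

    @property
    def max_total(self) -> int:
        return sum(max(self.permissible[sub]) for sub in SUBSCALES)

    def validate(self, sub: str, score: int) -> None:
        if sub not in self.permissible:
            raise SubscaleValueError(f"unknown subscale {sub!r}")
        if score not in self.permissible[sub]:
            raise SubscaleValueError(
                f"score {score!r} is not a permissible {sub} value "
                f"(allowed: {sorted(self.permissible[sub])})")


DEFAULT_CODING = SubscaleCoding()


@dataclass(frozen=True)
class DesignRAssessment:
    """One DESIGN-R 2020 rating of a single pressure injury.

    ``depth`` is the instrument's D code (kept as-is, e.g. 2 for d2); it is
    stored for completeness but excluded from the total and from dummy
    coding.  ``None`` marks a missing subscale.
    """

    exudate: int | None
    size: int | None
    inflammation_infection: int | None
    granulation: int | None
    necrotic: int | None
    pocket: int | None
    depth: int | str | None = None

    def validated(self, coding: SubscaleCoding = DEFAULT_CODING) -> "DesignRAssessment":
        for sub in SUBSCALES:
            value = getattr(self, sub)
            if value is not None:
                coding.validate(sub, value)
        return self


@dataclass(frozen=True)
class SubscaleDummies:
    """The mutually exclusive severe/mild indicator pair for one subscale."""

    large: int
    small: int

    def __post_init__(self) -> None:
        if self.large not in (0, 1) or self.small not in (0, 1):
            raise ValueError("dummies must be 0/1")
        if self.large and self.small:
            raise ValueError("large and small cannot both be 1")


def total_score(a: DesignRAssessment,
                coding: SubscaleCoding = DEFAULT_CODING) -> int:
    """Total DESIGN-R 2020 severity: the sum of the six non-depth subscales.

    Raises :class:`MissingSubscaleError` when any subscale is missing and
    :class:`SubscaleValueError` when a score is outside the permissible set.
    """
    total = 0
    for sub in SUBSCALES:
        value = getattr(a, sub)
        if value is None:
            raise MissingSubscaleError(f"subscale {sub!r} is missing")
        coding.validate(sub, value)
        total += int(value)
    return total


def binarize_subscale(name: str, score: int,
                      coding: SubscaleCoding = DEFAULT_CODING) -> SubscaleDummies:
    """Dummy-code one subscale score into its (large, small) indicator pair.

    Score 0 maps to (0, 0); a score in the severe partition maps to (1, 0)
    and one in the mild partition to (0, 1).
    """
    coding.validate(name, score)
    if score == 0:
        return SubscaleDummies(0, 0)
    if score in coding.large[name]:
        return SubscaleDummies(1, 0)
    return SubscaleDummies(0, 1)


def score_change(y_t: int, y_ts: int) -> int:
    """Signed change d = y_{t+s} - y_t between two total scores of one PI.

    Negative values indicate healing; no transformation is applied because
    changes are frequently negative.
    """
    return int(y_ts) - int(y_t)
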