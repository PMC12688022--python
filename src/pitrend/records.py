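"""Assessment-record tables: schema, validation, and the mapping from
longitudinal records to modelled score-change observations.

The canonical container is a pandas DataFrame with one row per
assessment of one pressure injury:

    pi_id, day, depth?, e, s, i, g, n, p, age?, <binary covariates...>

``day`` counts from the first assessment of that PI (day 0).  Derived
quantities — totals, changes, durations, subscale dummies — are always
computed, never read from the file.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .designr import (DEFAULT_CODING, SUBSCALE_LETTERS, SubscaleCoding,
                      binarize_subscale)
from .model import KNOWN_PREDICTORS, ScoreChangeObservation

__all__ = ["REQUIRED_COLUMNS", "RecordValidationError", "validate_records",
           "exclude_single_assessment", "compute_totals",
           "build_observations"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pi_id", "day", "e", "s", "i", "g", "n", "p")
OPTIONAL_COLUMNS = ("depth", "age", "total")
FLAG_COLUMNS = tuple(name for name in KNOWN_PREDICTORS
                     if name not in ("duration_day0", "duration_day0_sq",
                                     "baseline_score", "latest_score", "age")
                     and not name.endswith(("_large", "_small")))

_LETTER_TO_SUBSCALE = {v: k for k, v in SUBSCALE_LETTERS.items()}


class RecordValidationError(ValueError):
    """Itemized validation failure; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        super().__init__(
            "assessment records failed validation:\n  - "
            + "\n  - ".join(problems))
        self.problems = problems


def validate_records(df: pd.DataFrame,
                     coding: SubscaleCoding = DEFAULT_CODING) -> None:
    """Raise :class:`RecordValidationError` listing every problem found."""
    problems: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    allowed = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS) | set(FLAG_COLUMNS)
    for col in df.columns:
        if col not in allowed:
            problems.append(f"unknown column {col!r}")
    if problems:
        raise RecordValidationError(problems)

    for letter in ("e", "s", "i", "g", "n", "p"):
        sub = _LETTER_TO_SUBSCALE[letter]
        for row, value in df[letter].items():
            if pd.isna(value) or value not in coding.permissible[sub]:
                problems.append(
                    f"row {row}: column {letter!r} value {value!r} is not a "
                    f"permissible {sub} score")
    for col in FLAG_COLUMNS:
        if col in df.columns:
            bad = ~df[col].isin([0, 1])
            for row in df.index[bad]:
                problems.append(f"row {row}: column {col!r} must be 0/1, "
                                f"got {df.at[row, col]!r}")
    if (df["day"] < 0).any() or (df["day"] != df["day"].astype(int)).any():
        problems.append("column 'day' must hold non-negative integers")
    for pid, grp in df.groupby("pi_id", sort=False):
        days = grp["day"].to_numpy()
        if len(days) and days[0] != 0:
            problems.append(f"PI {pid!r}: first assessment must be day 0")
        if np.any(np.diff(days) <= 0):
            problems.append(f"PI {pid!r}: day indices must strictly increase")
    if problems:
        raise RecordValidationError(problems)


def exclude_single_assessment(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop PIs assessed only once (no change is observable for them)."""
    counts = df.groupby("pi_id")["day"].size()
    excluded = sorted(counts.index[counts < 2])
    if excluded:
        logger.warning("excluding %d PI(s) with a single assessment: %s",
                       len(excluded), ", ".join(map(str, excluded)))
        df = df[~df["pi_id"].isin(excluded)].reset_index(drop=True)
    return df, excluded


def compute_totals(df: pd.DataFrame) -> pd.Series:
    """Total severity score per row: the sum of the six non-depth subscales."""
    return df[["e", "s", "i", "g", "n", "p"]].sum(axis=1)


def build_observations(df: pd.DataFrame,
                       coding: SubscaleCoding = DEFAULT_CODING,
                       ) -> list[ScoreChangeObservation]:
    """Pair consecutive assessments of each PI into score-change
    observations, deriving every covariate the model can use.

    When a ``total`` column is present it overrides the subscale sum as
    the severity value (the synthetic generator uses this to carry
    continuous trajectories); dummies always come from the subscales.
    """
    observations: list[ScoreChangeObservation] = []
    for pid, grp in df.groupby("pi_id", sort=True):
        grp = grp.sort_values("day")
        totals = (grp["total"] if "total" in grp.columns
                  else compute_totals(grp)).to_numpy(dtype=float)
        days = grp["day"].to_numpy(dtype=float)
        baseline = float(totals[0])
        rows = grp.to_dict("records")
        for j in range(len(rows) - 1):
            here = rows[j]
            cov: dict[str, float] = {
                "baseline_score": baseline,
                "latest_score": float(totals[j]),
            }
            if "age" in grp.columns and not pd.isna(here.get("age")):
                cov["age"] = float(here["age"])
            for letter in ("e", "s", "i", "g", "n", "p"):
                sub = _LETTER_TO_SUBSCALE[letter]
                dummies = binarize_subscale(sub, int(here[letter]), coding)
                cov[f"{letter}_large"] = float(dummies.large)
                cov[f"{letter}_small"] = float(dummies.small)
            for col in FLAG_COLUMNS:
                if col in grp.columns:
                    cov[col] = float(here[col])
            observations.append(ScoreChangeObservation(
                pi_id=str(pid),
                duration_day0=float(days[j]),
                duration_next=float(days[j + 1] - days[j]),
                d=float(totals[j + 1] - totals[j]),
                covariates=cov))
    return observations
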