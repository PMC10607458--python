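"""Cohort-level summaries and group comparisons of per-participant results.

Aggregates per-participant blink rates and eye scores into group means,
compares groups with a two-sided t-test (Student's pooled-variance by
default, Welch optionally), and flags participants at or above a score
threshold.  Display values are rounded half-up to one decimal, matching
conventional clinical-table formatting; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateStatisticError,
    EmptyDataError,
    InvalidParameterError,
)

__all__ = [
    "Group",
    "ParticipantRecord",
    "GroupSummary",
    "round_half_up",
    "group_means",
    "compare_groups",
    "flag_mild_or_worse",
    "records_to_frame",
    "frame_to_records",
]

Group = Literal["CONTROL", "DED"]
TTestVariant = Literal["student", "welch"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.25 -> 0.3 at one decimal)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's demographics and per-recording results."""

    id: str
    group: str
    age: float
    sex: str
    full_rate_per_min: float
    partial_rate_per_min: float
    eye_score: int
    video_duration_s: float

    def __post_init__(self) -> None:
        if self.group not in ("CONTROL", "DED"):
            raise InvalidParameterError(
                f"group must be 'CONTROL' or 'DED', got {self.group!r}"
            )
        for name in ("age", "full_rate_per_min", "partial_rate_per_min",
                     "video_duration_s"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic means of a group's columns, with display rounding."""

    group: str
    n: int
    mean_age: float
    mean_full_rate: float
    mean_partial_rate: float
    mean_eye_score: float
    mean_duration: float
    sex_counts: dict

    def display(self, ndigits: int = 1) -> dict:
        """Means rounded half-up for table display."""
        return {
            "group": self.group,
            "n": self.n,
            "age": round_half_up(self.mean_age, ndigits),
            "full_rate": round_half_up(self.mean_full_rate, ndigits),
            "partial_rate": round_half_up(self.mean_partial_rate, ndigits),
            "eye_score": round_half_up(self.mean_eye_score, ndigits),
            "duration": round_half_up(self.mean_duration, ndigits),
            "sex_counts": dict(self.sex_counts),
        }


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    return [
        ParticipantRecord(
            id=str(row["id"]),
            group=str(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            full_rate_per_min=float(row["full_rate_per_min"]),
            partial_rate_per_min=float(row["partial_rate_per_min"]),
            eye_score=int(row["eye_score"]),
            video_duration_s=float(row["video_duration_s"]),
        )
        for _, row in df.iterrows()
    ]


def group_means(
    records: Sequence[ParticipantRecord], group: str
) -> GroupSummary:
    """Column means for one group (empty group is an error)."""
    members = [r for r in records if r.group == group]
    if not members:
        raise EmptyDataError(f"no records in group {group!r}")
    df = records_to_frame(members)
    return GroupSummary(
        group=group,
        n=len(members),
        mean_age=float(df["age"].mean()),
        mean_full_rate=float(df["full_rate_per_min"].mean()),
        mean_partial_rate=float(df["partial_rate_per_min"].mean()),
        mean_eye_score=float(df["eye_score"].mean()),
        mean_duration=float(df["video_duration_s"].mean()),
        sex_counts=df["sex"].value_counts().to_dict(),
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    variant: TTestVariant = "student",
) -> tuple[float, float]:
    """Two-sided t-test between two groups of values.

    ``student`` (default) is the classical pooled-variance test; ``welch``
    drops the equal-variance assumption.  Returns (t statistic, p-value).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs at least two values")
    if variant not in ("student", "welch"):
        raise InvalidParameterError(f"unknown t-test variant {variant!r}")
    result = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    t, p = float(result.statistic), float(result.pvalue)
    if math.isnan(t) or math.isnan(p):
        raise DegenerateStatisticError(
            "t statistic undefined (zero variance in both groups)"
        )
    return t, p


def flag_mild_or_worse(
    records: Sequence[ParticipantRecord], score_threshold: int = 4
) -> list[ParticipantRecord]:
    """Participants whose eye score meets or exceeds the threshold."""
    return [r for r in records if r.eye_score >= score_threshold]
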