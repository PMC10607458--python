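"""The 10-point eye healthiness score and dry-eye-disease (DED) categories.

The score combines two video-derived blink metrics with three questionnaire
risk factors, each contributing fixed points:

    full blink rate  > 30 per min   3 points
    partial blinks   >  5 per min   3 points
    dry and gritty feeling          2 points
    woman over 50 years old         1 point
    regular contact-lens wearing    1 point
                                   --------
    maximum                        10 points

All rate and age comparisons are strict (a rate of exactly 30/min or an age
of exactly 50 scores nothing for that component).  Totals of 0-3 are
considered normal, 4-6 mild DED (the app-level alert threshold is 4), and
7-10 severe DED warranting a clinical visit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .detect import BlinkMetrics
from .exceptions import InvalidParameterError

__all__ = [
    "FULL_RATE_CUTOFF",
    "PARTIAL_RATE_CUTOFF",
    "WOMAN_AGE_CUTOFF",
    "ALERT_THRESHOLD",
    "Category",
    "QuestionnaireRecord",
    "ScoreBreakdown",
    "EyeHealthReport",
    "score",
    "score_rates",
    "categorize",
    "build_report",
]

FULL_RATE_CUTOFF: float = 30.0  # blinks/min, strict
PARTIAL_RATE_CUTOFF: float = 5.0  # partial blinks/min, strict
WOMAN_AGE_CUTOFF: float = 50.0  # years, strict
ALERT_THRESHOLD: int = 4  # total score at which the mild-DED alert fires


class Category(str, enum.Enum):
    NORMAL = "NORMAL"
    MILD_DED = "MILD_DED"
    SEVERE_DED = "SEVERE_DED"


@dataclass(frozen=True)
class QuestionnaireRecord:
    """Self-reported inputs to the non-video score components.

    ``dry_gritty`` is the foreign-body sensation symptom;
    ``regular_contact_lens`` means regular (not occasional) wear.
    """

    age: float
    sex: str  # "F" or "M"
    dry_gritty: bool
    regular_contact_lens: bool

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise InvalidParameterError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age < 18:
            raise InvalidParameterError("age must be >= 18 (study eligibility)")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component points of the eye healthiness score."""

    blink_points: int
    partial_points: int
    gritty_points: int
    woman_over_50_points: int
    lens_points: int

    @property
    def total(self) -> int:
        return (
            self.blink_points
            + self.partial_points
            + self.gritty_points
            + self.woman_over_50_points
            + self.lens_points
        )


@dataclass(frozen=True)
class EyeHealthReport:
    """Score breakdown with its category and the inputs that produced it."""

    breakdown: ScoreBreakdown
    category: Category
    alert: bool
    full_rate_per_min: float
    partial_rate_per_min: float
    questionnaire: QuestionnaireRecord

    @property
    def total(self) -> int:
        return self.breakdown.total


def score_rates(
    full_rate_per_min: float,
    partial_rate_per_min: float,
    q: QuestionnaireRecord,
) -> ScoreBreakdown:
    """Score directly from per-minute rates and a questionnaire record."""
    if full_rate_per_min < 0 or partial_rate_per_min < 0:
        raise InvalidParameterError("blink rates must be nonnegative")
    return ScoreBreakdown(
        blink_points=3 if full_rate_per_min > FULL_RATE_CUTOFF else 0,
        partial_points=3 if partial_rate_per_min > PARTIAL_RATE_CUTOFF else 0,
        gritty_points=2 if q.dry_gritty else 0,
        woman_over_50_points=1 if (q.sex == "F" and q.age > WOMAN_AGE_CUTOFF) else 0,
        lens_points=1 if q.regular_contact_lens else 0,
    )


def score(metrics: BlinkMetrics, q: QuestionnaireRecord) -> ScoreBreakdown:
    """Score from a recording's blink metrics (duration-normalized rates)."""
    return score_rates(metrics.full_rate_per_min, metrics.partial_rate_per_min, q)


def categorize(total: int) -> Category:
    """Map a total score to its DED category (0-3 / 4-6 / 7-10)."""
    if not 0 <= total <= 10:
        raise InvalidParameterError(f"total score must be in [0, 10], got {total}")
    if total <= 3:
        return Category.NORMAL
    if total <= 6:
        return Category.MILD_DED
    return Category.SEVERE_DED


def build_report(metrics: BlinkMetrics, q: QuestionnaireRecord) -> EyeHealthReport:
    """Full report: breakdown, category, and the >= 4 alert flag."""
    breakdown = score(metrics, q)
    return EyeHealthReport(
        breakdown=breakdown,
        category=categorize(breakdown.total),
        alert=breakdown.total >= ALERT_THRESHOLD,
        full_rate_per_min=metrics.full_rate_per_min,
        partial_rate_per_min=metrics.partial_rate_per_min,
        questionnaire=q,
    )
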