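"""Blink detection and classification on EAR time series.

Two detection rules are provided.

*Fixed rule*: a blink is any run of at least ``min_run`` consecutive
non-missing frames whose EAR is at or below a fixed threshold (default
0.163).  This works for eyes whose open-plateau and closed levels bracket
the threshold, but undercounts in individuals with shallow closures
(partial blinks) or unusual open/closed EAR levels.

*Dynamic dual-threshold rule*: the thresholds are derived from the
individual's own EAR range over the recording,

    full_threshold    = (0.1281 / 0.27527) * (MaxEAR - MinEAR)
    partial_threshold = 1.4 * full_threshold

An event is a run of at least ``min_run`` consecutive frames at or below the
*partial* threshold; it is classified FULL if its minimum EAR reaches the
full threshold and PARTIAL otherwise.  Segmenting at the partial threshold
and classifying by the event minimum prevents the entry and exit frames of a
full blink (which necessarily traverse the partial band) from being counted
as an extra partial blink.

Missing frames break runs, so landmark dropout shortens or suppresses
events (monotone undercounting); an optional ``bridge_gap`` can merge runs
separated by at most that many non-qualifying frames.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ear import EARSeries, EARSummary
from .exceptions import EmptyDataError, InvalidParameterError

__all__ = [
    "DYNAMIC_COEFFICIENT",
    "PARTIAL_FACTOR",
    "FIXED_EAR_THRESHOLD",
    "DEFAULT_MIN_RUN",
    "BlinkKind",
    "ThresholdPair",
    "BlinkEvent",
    "BlinkMetrics",
    "count_blinks_fixed",
    "dynamic_thresholds",
    "segment_events",
    "compute_metrics",
]

#: Slope of the dynamic full-blink threshold vs. the individual EAR span.
DYNAMIC_COEFFICIENT: float = 0.1281 / 0.27527
#: Partial threshold as a multiple of the full threshold (40% higher).
PARTIAL_FACTOR: float = 1.4
#: Default fixed-rule EAR threshold.
FIXED_EAR_THRESHOLD: float = 0.163
#: Minimum number of consecutive below-threshold frames that counts as a blink.
DEFAULT_MIN_RUN: int = 3

Reference = Literal["absolute", "offset"]


class BlinkKind(str, enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class ThresholdPair:
    """Full- and partial-blink EAR thresholds.

    The canonical pair, built by :func:`dynamic_thresholds` or
    :meth:`from_full`, couples them as partial = 1.4 x full.  Decoupled
    pairs (still requiring 0 <= full <= partial) may be supplied directly
    for sensitivity analyses that vary one threshold at a time.
    """

    full: float
    partial: float

    def __post_init__(self) -> None:
        if self.full < 0 or self.partial < self.full:
            raise InvalidParameterError(
                "thresholds must satisfy 0 <= full <= partial"
            )

    @classmethod
    def from_full(cls, full: float) -> "ThresholdPair":
        """The coupled pair: partial exactly 1.4 x full."""
        return cls(full=full, partial=PARTIAL_FACTOR * full)

    @property
    def is_coupled(self) -> bool:
        """True when partial = 1.4 x full to within 1e-12."""
        return abs(self.partial - PARTIAL_FACTOR * self.full) <= 1e-12


@dataclass(frozen=True)
class BlinkEvent:
    """A contiguous below-threshold excursion, classified full or partial."""

    start_frame: int
    end_frame: int
    min_ear: float
    kind: BlinkKind

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class BlinkMetrics:
    """Event tallies and per-minute rates for one recording.

    ``open_close_ratio_pct`` is reported as 100 * MinEAR / MaxEAR.  That
    definition is a package convention, not validated against any clinical
    reference, and is excluded from all scoring.
    """

    full_count: int
    partial_count: int
    duration: float
    full_rate_per_min: float
    partial_rate_per_min: float
    open_close_ratio_pct: float


def _qualifying_runs(
    values: np.ndarray, threshold: float, min_run: int, bridge_gap: int = 0
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive finite values <= threshold.

    Runs separated by at most ``bridge_gap`` non-qualifying frames are
    merged; only merged runs spanning >= min_run frames are returned.
    """
    ok = np.isfinite(values) & (values <= threshold)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    # split where the gap between qualifying frames exceeds the bridge
    breaks = np.flatnonzero(np.diff(idx) > bridge_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
    return [(s, e) for s, e in runs if e - s + 1 >= min_run]


def count_blinks_fixed(
    series: EARSeries,
    threshold: float = FIXED_EAR_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    bridge_gap: int = 0,
) -> int:
    """Blink count under the fixed-threshold rule.

    Each maximal run of ``min_run`` or more consecutive non-missing frames
    with EAR <= ``threshold`` counts as exactly one blink.  Missing frames
    break runs.
    """
    if min_run < 1:
        raise InvalidParameterError("min_run must be >= 1")
    if series.n_frames == 0:
        raise EmptyDataError("empty EAR series")
    return len(_qualifying_runs(series.ear, threshold, min_run, bridge_gap))


def dynamic_thresholds(summary: EARSummary) -> ThresholdPair:
    """Personalized thresholds from an individual's EAR range.

    full = (0.1281 / 0.27527) * (MaxEAR - MinEAR); partial = 1.4 * full.
    """
    if summary.max_ear < summary.min_ear:
        raise InvalidParameterError("invalid summary: max_ear < min_ear")
    full = DYNAMIC_COEFFICIENT * summary.span
    return ThresholdPair.from_full(full)


def segment_events(
    series: EARSeries,
    thresholds: ThresholdPair,
    min_run: int = DEFAULT_MIN_RUN,
    reference: Reference = "absolute",
    bridge_gap: int = 0,
) -> list[BlinkEvent]:
    """Detect and classify blink events with the dual-threshold rule.

    Events are maximal runs of >= min_run consecutive non-missing frames at
    or below the partial threshold; each is FULL if its minimum reaches the
    full threshold, PARTIAL otherwise.  ``reference`` selects what is
    compared against the thresholds:

    - ``"absolute"`` (default): the raw EAR value, exactly as the threshold
      formula is printed.  Note that when MinEAR is far above zero the full
      threshold may be unreachable in this mode.
    - ``"offset"``: the excursion depth ``ear - MinEAR``, which makes
      detection invariant to a constant shift of the whole trace.

    Returned events are ordered and non-overlapping; ``min_ear`` is always
    the raw series minimum over the event.
    """
    if min_run < 1:
        raise InvalidParameterError("min_run must be >= 1")
    values = series.ear
    if reference == "offset":
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return []
        compare = values - finite.min()
    elif reference == "absolute":
        compare = values
    else:
        raise InvalidParameterError(f"unknown threshold reference {reference!r}")

    events: list[BlinkEvent] = []
    for start, end in _qualifying_runs(compare, thresholds.partial, min_run, bridge_gap):
        window = compare[start : end + 1]
        window_min = float(np.nanmin(window))
        kind = BlinkKind.FULL if window_min <= thresholds.full else BlinkKind.PARTIAL
        raw_min = float(np.nanmin(values[start : end + 1]))
        events.append(
            BlinkEvent(start_frame=start, end_frame=end, min_ear=raw_min, kind=kind)
        )
    return events


def compute_metrics(
    events: Sequence[BlinkEvent], series: EARSeries
) -> BlinkMetrics:
    """Tally events by kind and normalize to per-minute rates.

    Rates use the actual recording duration (count * 60 / duration), so
    recordings a few seconds longer or shorter than a minute are comparable.
    """
    duration = series.duration
    if duration <= 0:
        raise InvalidParameterError("recording duration must be positive")
    full_count = sum(1 for e in events if e.kind is BlinkKind.FULL)
    partial_count = sum(1 for e in events if e.kind is BlinkKind.PARTIAL)
    finite = series.ear[np.isfinite(series.ear)]
    if finite.size and finite.max() > 0:
        open_close = 100.0 * float(finite.min()) / float(finite.max())
    else:
        open_close = float("nan")
    return BlinkMetrics(
        full_count=full_count,
        partial_count=partial_count,
        duration=duration,
        full_rate_per_min=full_count * 60.0 / duration,
        partial_rate_per_min=partial_count * 60.0 / duration,
        open_close_ratio_pct=open_close,
    )
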