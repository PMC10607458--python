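"""End-to-end analysis of one EAR series under a RunConfig.

Chains summarize -> thresholds -> event segmentation -> metrics, which is
the whole per-recording computation: the caller supplies an EARSeries (from
landmarks, a file, or the synthetic generator) and gets back the summary,
the thresholds actually used, the classified events and the rate metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .detect import (
    BlinkEvent,
    BlinkKind,
    BlinkMetrics,
    ThresholdPair,
    _qualifying_runs,
    compute_metrics,
    dynamic_thresholds,
    segment_events,
)
from .ear import EARSeries, EARSummary, summarize

__all__ = ["AnalysisResult", "analyze_series"]

import numpy as np


@dataclass(frozen=True)
class AnalysisResult:
    """Everything computed for one recording, plus the config used."""

    summary: EARSummary
    thresholds: ThresholdPair | None
    events: tuple[BlinkEvent, ...]
    metrics: BlinkMetrics
    config: RunConfig


def analyze_series(series: EARSeries, config: RunConfig = RunConfig()) -> AnalysisResult:
    """Run the configured detection pipeline on one series.

    In ``fixed`` threshold mode every qualifying run below the single fixed
    threshold is counted as a full blink (the fixed rule has no partial
    class); in ``dynamic`` mode the dual thresholds are derived from the
    series' own summary and events are classified full/partial.
    """
    summary = summarize(
        series,
        robust=config.robust_summary,
        percentiles=config.robust_percentiles,
    )
    if config.threshold_mode == "fixed":
        runs = _qualifying_runs(
            series.ear, config.fixed_threshold, config.min_run, config.bridge_gap
        )
        events = tuple(
            BlinkEvent(
                start_frame=s,
                end_frame=e,
                min_ear=float(np.nanmin(series.ear[s : e + 1])),
                kind=BlinkKind.FULL,
            )
            for s, e in runs
        )
        thresholds = None
    else:
        thresholds = dynamic_thresholds(summary)
        events = tuple(
            segment_events(
                series,
                thresholds,
                min_run=config.min_run,
                reference=config.reference,  # type: ignore[arg-type]
                bridge_gap=config.bridge_gap,
            )
        )
    metrics = compute_metrics(events, series)
    return AnalysisResult(
        summary=summary,
        thresholds=thresholds,
        events=events,
        metrics=metrics,
        config=config,
    )
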