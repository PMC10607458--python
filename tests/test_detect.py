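"""Fixed- and dynamic-threshold blink detection and rate metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkscore.detect import (
    BlinkKind,
    ThresholdPair,
    compute_metrics,
    count_blinks_fixed,
    dynamic_thresholds,
    segment_events,
)
from blinkscore.ear import EARSummary, summarize
from blinkscore.exceptions import EmptyDataError, InvalidParameterError

from conftest import series_from

OPEN = 0.25


def dip_series(*dips, n=60, depth=0.05, fps=30.0):
    """Open-eye series with below-threshold dips at given (start, length)."""
    values = [OPEN] * n
    for start, length in dips:
        for i in range(start, start + length):
            values[i] = depth
    return series_from(values, fps=fps)


class TestFixedRule:
    def test_no_dip_no_blink(self):
        assert count_blinks_fixed(dip_series()) == 0

    def test_three_frame_dip_is_one_blink(self):
        assert count_blinks_fixed(dip_series((10, 3))) == 1

    def test_two_frame_dip_is_no_blink(self):
        assert count_blinks_fixed(dip_series((10, 2))) == 0

    def test_two_dips_separated_by_one_open_frame(self):
        assert count_blinks_fixed(dip_series((10, 4), (15, 4))) == 2

    def test_boundary_value_counts(self):
        # the rule is EAR <= threshold, inclusive
        s = series_from([OPEN, 0.163, 0.163, 0.163, OPEN])
        assert count_blinks_fixed(s, threshold=0.163) == 1

    def test_missing_frames_break_runs(self):
        s = series_from([OPEN, 0.1, 0.1, None, 0.1, 0.1, OPEN])
        assert count_blinks_fixed(s) == 0
        s2 = series_from([OPEN, 0.1, 0.1, 0.1, None, 0.1, 0.1, 0.1, OPEN])
        assert count_blinks_fixed(s2) == 2

    def test_bridge_gap_merges_interrupted_run(self):
        s = series_from([OPEN, 0.1, 0.1, None, 0.1, 0.1, OPEN])
        assert count_blinks_fixed(s, bridge_gap=1) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(EmptyDataError):
            count_blinks_fixed(series_from([]))

    def test_min_run_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            count_blinks_fixed(dip_series((10, 3)), min_run=0)

    def test_matches_brute_force_oracle_on_random_series(self):
        def oracle(values, threshold, min_run):
            count = run = 0
            for v in values:
                if v is not None and v <= threshold:
                    run += 1
                else:
                    count += run >= min_run
                    run = 0
            return count + (run >= min_run)

        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 80))
            values = [
                None if rng.random() < 0.05
                else (0.1 if rng.random() < 0.35 else OPEN)
                for _ in range(n)
            ]
            s = series_from(values)
            for min_run in (1, 2, 3):
                assert count_blinks_fixed(s, min_run=min_run) == oracle(
                    values, 0.163, min_run
                )


def summary(max_ear, min_ear):
    avg = 0.5 * (max_ear + min_ear)
    return EARSummary(average_ear=avg, max_ear=max_ear, min_ear=min_ear,
                      n_frames=100, n_missing=0)


class TestDynamicThresholds:
    def test_reference_span_gives_exact_coefficient(self):
        pair = dynamic_thresholds(summary(0.27527, 0.0))
        assert pair.full == pytest.approx(0.1281, abs=1e-12)
        assert pair.partial == pytest.approx(1.4 * 0.1281, abs=1e-12)

    def test_zero_span_gives_zero_thresholds(self):
        pair = dynamic_thresholds(summary(0.2, 0.2))
        assert pair.full == 0.0 and pair.partial == 0.0

    def test_quarter_span_values(self):
        pair = dynamic_thresholds(summary(0.30, 0.05))
        assert pair.full == pytest.approx(0.1163398, rel=1e-5)
        assert pair.partial == pytest.approx(0.1628757, rel=1e-5)

    def test_inverted_summary_unconstructible(self):
        with pytest.raises(InvalidParameterError):
            EARSummary(average_ear=0.2, max_ear=0.1, min_ear=0.3,
                       n_frames=10, n_missing=0)

    def test_pair_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            ThresholdPair(full=0.2, partial=0.1)
        with pytest.raises(InvalidParameterError):
            ThresholdPair(full=-0.1, partial=0.1)

    def test_coupled_constructor(self):
        assert ThresholdPair.from_full(0.1).is_coupled
        assert not ThresholdPair(full=0.1, partial=0.2).is_coupled


class TestSegmentEvents:
    def make(self, *levels):
        """Series with one dip per level: 2-frame ramps + 3-frame bottom."""
        values = [OPEN] * 5
        for level in levels:
            ramp = np.linspace(OPEN, level, 4)[1:-1]
            values += list(ramp) + [level] * 3 + list(ramp[::-1]) + [OPEN] * 5
        return series_from(values)

    def thresholds_for(self, series):
        return dynamic_thresholds(summarize(series))

    def test_deep_dip_is_full(self):
        s = self.make(0.02)
        events = segment_events(s, self.thresholds_for(s))
        assert [e.kind for e in events] == [BlinkKind.FULL]

    def test_shallow_dip_is_partial(self):
        s = self.make(0.02, 0.135)  # full dip sets the span
        events = segment_events(s, self.thresholds_for(s))
        assert [e.kind for e in events] == [BlinkKind.FULL, BlinkKind.PARTIAL]

    def test_dip_above_partial_band_not_an_event(self):
        s = self.make(0.02, 0.2)
        events = segment_events(s, self.thresholds_for(s))
        assert len(events) == 1 and events[0].kind is BlinkKind.FULL

    def test_full_blink_ramp_not_double_counted_as_partial(self):
        # entry/exit frames traverse the partial band but merge into one event
        s = self.make(0.02, 0.02, 0.02)
        events = segment_events(s, self.thresholds_for(s))
        assert len(events) == 3
        assert all(e.kind is BlinkKind.FULL for e in events)

    def test_events_ordered_and_non_overlapping(self):
        s = self.make(0.02, 0.135, 0.02, 0.135)
        events = segment_events(s, self.thresholds_for(s))
        for a, b in zip(events, events[1:]):
            assert a.end_frame < b.start_frame

    def test_conservation_full_plus_partial(self):
        s = self.make(0.02, 0.135, 0.135, 0.02)
        events = segment_events(s, self.thresholds_for(s))
        full = sum(e.kind is BlinkKind.FULL for e in events)
        partial = sum(e.kind is BlinkKind.PARTIAL for e in events)
        assert full + partial == len(events)

    def test_lower_full_threshold_never_raises_full_count(self):
        # vary full threshold with the partial threshold held fixed
        s = self.make(0.02, 0.10, 0.135)
        partial = 0.16
        fulls = [0.15, 0.12, 0.08, 0.01]
        counts = []
        for f in fulls:
            events = segment_events(s, ThresholdPair(full=f, partial=partial))
            counts.append(
                (sum(e.kind is BlinkKind.FULL for e in events),
                 sum(e.kind is BlinkKind.PARTIAL for e in events))
            )
        for (f1, p1), (f2, p2) in zip(counts, counts[1:]):
            assert f2 <= f1 and p2 >= p1

    def test_offset_mode_invariant_under_constant_shift(self):
        base = self.make(0.02, 0.135)
        shifted = series_from(base.ear + 0.1)
        pair = self.thresholds_for(base)  # same span either way
        kinds = lambda s, ref: [
            e.kind for e in segment_events(s, pair, reference=ref)
        ]
        assert kinds(base, "offset") == kinds(shifted, "offset")
        # absolute mode is not shift-invariant: raised trace misses thresholds
        assert kinds(shifted, "absolute") != kinds(base, "absolute")

    def test_min_ear_reports_raw_series_minimum(self):
        s = self.make(0.02)
        (event,) = segment_events(s, self.thresholds_for(s))
        assert event.min_ear == pytest.approx(0.02)
        assert event.n_frames == event.end_frame - event.start_frame + 1


class TestComputeMetrics:
    def test_no_events_zero_rates(self):
        s = series_from([OPEN] * 1800)  # 60 s at 30 fps
        m = compute_metrics([], s)
        assert m.full_count == m.partial_count == 0
        assert m.full_rate_per_min == m.partial_rate_per_min == 0.0

    def test_rates_scale_to_per_minute(self):
        s = dip_series(n=1800)
        from blinkscore.detect import BlinkEvent

        events = [
            BlinkEvent(10 * i, 10 * i + 3, 0.02, BlinkKind.FULL)
            for i in range(10)
        ] + [
            BlinkEvent(1000 + 10 * i, 1000 + 10 * i + 3, 0.13, BlinkKind.PARTIAL)
            for i in range(2)
        ]
        m = compute_metrics(events, s)
        assert m.full_rate_per_min == pytest.approx(10.0)
        assert m.partial_rate_per_min == pytest.approx(2.0)

    def test_half_minute_doubles_rate(self):
        s = series_from([OPEN] * 900)  # 30 s at 30 fps
        from blinkscore.detect import BlinkEvent

        events = [
            BlinkEvent(5 * i, 5 * i + 3, 0.02, BlinkKind.FULL) for i in range(15)
        ]
        m = compute_metrics(events, s)
        assert m.full_rate_per_min == pytest.approx(30.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_metrics([], series_from([]))

    def test_open_close_ratio_definition(self):
        s = series_from([0.25, 0.05, 0.25])
        m = compute_metrics([], s)
        assert m.open_close_ratio_pct == pytest.approx(100 * 0.05 / 0.25)


@given(
    st.lists(st.sampled_from([0.25, 0.1, None]), min_size=1, max_size=40),
    st.integers(1, 4),
)
@settings(max_examples=150, derandomize=True)
def test_fixed_count_matches_run_definition(values, min_run):
    """Property: the count equals the number of maximal qualifying runs."""
    s = series_from(values)
    runs, run = [], 0
    for v in values:
        if v is not None and v <= 0.163:
            run += 1
        else:
            runs.append(run)
            run = 0
    runs.append(run)
    expected = sum(1 for r in runs if r >= min_run)
    assert count_blinks_fixed(s, min_run=min_run) == expected
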