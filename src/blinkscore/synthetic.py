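"""Synthetic EAR traces with known ground-truth blink events.

No public video or landmark data exist for this kind of recording, so the
generator emulates the signal a one-minute, fixed-frame-rate recording
produces: an open-eye plateau near EAR 0.25, trapezoidal full-blink dips
toward 0, shallower partial-blink dips whose bottom sits between the two
dynamic thresholds, additive Gaussian noise (clipped at 0, since EAR is
nonnegative), and optional landmark-dropout runs recorded as missing
frames.  Dips are trapezoidal — a short descent, at least three bottom
frames, a short ascent — so that a full blink's entry and exit frames
traverse the partial band, exercising the double-counting hazard the event
segmentation must handle.

Every generated series is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .detect import (
    DYNAMIC_COEFFICIENT,
    PARTIAL_FACTOR,
    BlinkEvent,
    BlinkKind,
)
from .ear import MISSING, EARSeries, EyeLandmarks
from .exceptions import InvalidParameterError, PlacementError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "make_ded_profile",
    "landmarks_for_ear",
]

#: Frames between consecutive events kept above threshold so runs never merge.
_MIN_EVENT_GAP = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Defaults describe a one-minute recording at 30 frames/s with an open-eye
    plateau at 0.25, full blinks bottoming at 0.02, and partial blinks
    reaching half the open-to-closed span (bottom 0.135 by default, which
    lies between the dynamic full and partial thresholds of the noise-free
    trace).
    """

    duration_s: float = 60.0
    fps: float = 30.0
    open_level: float = 0.25
    full_depth: float = 0.02
    partial_depth_fraction: float = 0.5
    n_full: int = 10
    n_partial: int = 2
    blink_len_frames: int = 3
    ramp_frames: int = 2
    noise_sd: float = 0.005
    dropout_runs: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise InvalidParameterError("duration and fps must be positive")
        if self.blink_len_frames < 3:
            raise InvalidParameterError("blink_len_frames must be >= 3")
        if self.ramp_frames < 0:
            raise InvalidParameterError("ramp_frames must be nonnegative")
        if self.n_full < 0 or self.n_partial < 0:
            raise InvalidParameterError("event counts must be nonnegative")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if not 0.0 < self.partial_depth_fraction < 1.0:
            raise InvalidParameterError("partial_depth_fraction must be in (0, 1)")
        if not self.full_depth < self.partial_bottom < self.open_level:
            raise InvalidParameterError(
                "depths must satisfy full_depth < partial bottom < open_level"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def partial_bottom(self) -> float:
        """EAR level partial dips descend to."""
        span = self.open_level - self.full_depth
        return self.open_level - self.partial_depth_fraction * span

    @property
    def expected_thresholds(self) -> tuple[float, float]:
        """(full, partial) thresholds of the noise-free trace."""
        full = DYNAMIC_COEFFICIENT * (self.open_level - self.full_depth)
        return full, PARTIAL_FACTOR * full


@dataclass(frozen=True)
class GroundTruth:
    """Placed events and intended counts for one generated series."""

    events: tuple[BlinkEvent, ...]
    n_full: int
    n_partial: int

    def __post_init__(self) -> None:
        placed_full = sum(1 for e in self.events if e.kind is BlinkKind.FULL)
        placed_partial = sum(1 for e in self.events if e.kind is BlinkKind.PARTIAL)
        if (placed_full, placed_partial) != (self.n_full, self.n_partial):
            raise InvalidParameterError("ground-truth counts disagree with events")


def _event_profile(spec: SyntheticSpec, bottom: float) -> np.ndarray:
    """Trapezoidal dip: descent, flat bottom, ascent (open level excluded)."""
    ramp = np.linspace(spec.open_level, bottom, spec.ramp_frames + 2)[1:-1]
    flat = np.full(spec.blink_len_frames, bottom)
    return np.concatenate([ramp, flat, ramp[::-1]])


def generate(spec: SyntheticSpec) -> tuple[EARSeries, GroundTruth]:
    """Build one synthetic EAR series and its ground truth.

    Events are placed without overlap at uniformly random positions (at
    least two open frames apart), kinds shuffled; noise is added after the
    shape and clipped at zero; dropout runs are applied last as missing
    frames.  Raises PlacementError when the requested events cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    n_events = spec.n_full + spec.n_partial
    event_len = 2 * spec.ramp_frames + spec.blink_len_frames
    needed = n_events * event_len + max(n_events - 1, 0) * _MIN_EVENT_GAP
    if needed > n_frames:
        raise PlacementError(
            f"cannot place {n_events} events of {event_len} frames in "
            f"{n_frames} frames"
        )

    ear = np.full(n_frames, spec.open_level, dtype=float)
    events: list[BlinkEvent] = []
    if n_events > 0:
        slack = n_frames - needed
        extra = rng.multinomial(slack, np.full(n_events + 1, 1.0 / (n_events + 1)))
        kinds = [BlinkKind.FULL] * spec.n_full + [BlinkKind.PARTIAL] * spec.n_partial
        kinds = [kinds[j] for j in rng.permutation(n_events)]
        cursor = 0
        for i, kind in enumerate(kinds):
            cursor += int(extra[i]) + (_MIN_EVENT_GAP if i > 0 else 0)
            bottom = spec.full_depth if kind is BlinkKind.FULL else spec.partial_bottom
            profile = _event_profile(spec, bottom)
            ear[cursor : cursor + profile.size] = profile
            events.append(
                BlinkEvent(
                    start_frame=cursor,
                    end_frame=cursor + profile.size - 1,
                    min_ear=bottom,
                    kind=kind,
                )
            )
            cursor += profile.size

    if spec.noise_sd > 0:
        ear = np.clip(ear + rng.normal(0.0, spec.noise_sd, n_frames), 0.0, None)

    for start, length in spec.dropout_runs:
        if start < 0 or length < 0 or start + length > n_frames:
            raise InvalidParameterError(
                f"dropout run ({start}, {length}) falls outside the recording"
            )
        ear[start : start + length] = MISSING

    series = EARSeries(ear=ear, fps=spec.fps)
    truth = GroundTruth(
        events=tuple(events), n_full=spec.n_full, n_partial=spec.n_partial
    )
    return series, truth


def make_ded_profile(
    kind: Literal["control", "ded"], seed: int | None = None
) -> SyntheticSpec:
    """Preset one-minute recording specs for the two study groups.

    Event counts are drawn near the observed group means (about 22 full and
    2.5 partial blinks/min in controls, about 37 and 6 in dry-eye patients)
    with dispersion clipped to the observed per-group ranges.
    """
    rng = np.random.default_rng(seed)
    if kind == "control":
        n_full = int(np.clip(round(rng.normal(22.2, 4.0)), 15, 30))
        n_partial = int(np.clip(round(rng.normal(2.5, 1.5)), 0, 8))
    elif kind == "ded":
        n_full = int(np.clip(round(rng.normal(37.4, 8.0)), 13, 64))
        n_partial = int(np.clip(round(rng.normal(5.8, 3.0)), 0, 14))
    else:
        raise InvalidParameterError(f"unknown profile kind {kind!r}")
    return SyntheticSpec(
        duration_s=60.0,
        fps=30.0,
        n_full=n_full,
        n_partial=n_partial,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def landmarks_for_ear(target_ear: float, width: float = 4.0) -> EyeLandmarks:
    """Geometric landmark set realizing a target EAR.

    A simple symmetric eye: corners ``width`` apart on the x-axis, lid points
    at x = width/4 and 3*width/4 with vertical half-opening scaled so the
    EAR formula returns ``target_ear`` exactly.  This is a geometric device
    for testing landmark pipelines, not an eyelid-kinematics model.
    """
    if target_ear < 0 or width <= 0:
        raise InvalidParameterError("target_ear must be >= 0 and width > 0")
    h = target_ear * width / 2.0
    return EyeLandmarks(
        p1=(0.0, 0.0),
        p2=(width / 4.0, h),
        p3=(3.0 * width / 4.0, h),
        p4=(width, 0.0),
        p5=(3.0 * width / 4.0, -h),
        p6=(width / 4.0, -h),
    )
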