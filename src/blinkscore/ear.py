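"""Per-frame eye-aspect-ratio (EAR) computation and EAR time-series handling.

The EAR of one eye is computed from six landmarks placed around the palpebral
fissure: the temporal corner (p1), two points on the upper lid (p2, p3), the
nasal corner (p4), and two points on the lower lid (p5, p6).  With ``||.||``
the Euclidean norm,

    EAR = (||p2 - p6|| + ||p3 - p5||) / (2 * ||p1 - p4||)

The ratio sits near 0.25 while the eye is open and collapses toward 0 as the
lids close, which makes the per-frame EAR trace a convenient one-dimensional
signal for blink detection.  Because it is a ratio of distances, EAR is
invariant under rotation, translation and uniform scaling of the landmark
set, so camera distance and head pose (in plane) do not matter.

Frames on which the landmark detector failed are carried through the series
as *missing* values (NaN) rather than dropped: downstream run-based blink
detection treats them as run breakers, reproducing the undercounting seen
when landmarks drop out (e.g. mask wearing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import EmptyDataError, GeometryError, InvalidParameterError

__all__ = [
    "MISSING",
    "is_missing",
    "EyeLandmarks",
    "LandmarkFrame",
    "EARSeries",
    "EARSummary",
    "compute_ear",
    "combine_eyes",
    "build_series",
    "summarize",
]

#: Sentinel for a frame with no usable EAR value (detector returned nothing).
MISSING: float = math.nan

EyeMode = Literal["mean", "left", "right", "min"]


def is_missing(value: float) -> bool:
    """True if ``value`` is the missing-frame marker (NaN)."""
    return isinstance(value, float) and math.isnan(value)


Point = tuple[float, float]


@dataclass(frozen=True)
class EyeLandmarks:
    """Six 2-D eye landmarks, in pixel units.

    Ordering: p1 temporal corner, p2/p3 upper lid, p4 nasal corner,
    p5/p6 lower lid (p6 below p2, p5 below p3).
    """

    p1: Point
    p2: Point
    p3: Point
    p4: Point
    p5: Point
    p6: Point

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5", "p6"):
            pt = getattr(self, name)
            if len(pt) != 2 or not all(math.isfinite(c) for c in pt):
                raise InvalidParameterError(
                    f"landmark {name} must be a finite 2-D point, got {pt!r}"
                )

    def as_array(self) -> np.ndarray:
        """Landmarks as a (6, 2) float array ordered p1..p6."""
        return np.array(
            [self.p1, self.p2, self.p3, self.p4, self.p5, self.p6], dtype=float
        )

    def transformed(
        self,
        scale: float = 1.0,
        angle: float = 0.0,
        offset: Point = (0.0, 0.0),
    ) -> "EyeLandmarks":
        """Apply a similarity transform (scale, rotate, translate) to all points."""
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        pts = scale * (self.as_array() @ rot.T) + np.asarray(offset, dtype=float)
        return EyeLandmarks(*(tuple(p) for p in pts))


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's eye landmarks.

    ``valid=False`` means the detector returned no landmarks for this frame;
    both eyes must then be absent and the frame becomes MISSING in the series.
    """

    frame_index: int
    timestamp: float | None = None
    left: EyeLandmarks | None = None
    right: EyeLandmarks | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InvalidParameterError("frame_index must be nonnegative")
        if not self.valid and (self.left is not None or self.right is not None):
            raise InvalidParameterError(
                "an invalid frame cannot carry landmarks (valid=False implies "
                "both eyes absent)"
            )


@dataclass
class EARSeries:
    """An ordered EAR trace at a fixed frame rate.

    Missing frames are NaN in ``ear``.  ``timestamps`` are in seconds and,
    when not supplied by the reader, derived as ``frame_index / fps``.
    """

    ear: np.ndarray
    fps: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ear = np.asarray(self.ear, dtype=float)
        if self.ear.ndim != 1:
            raise InvalidParameterError("ear must be one-dimensional")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")
        finite = self.ear[np.isfinite(self.ear)]
        if finite.size and finite.min() < 0:
            raise InvalidParameterError("EAR values must be nonnegative")
        if self.timestamps is None:
            self.timestamps = np.arange(self.ear.size, dtype=float) / self.fps
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != self.ear.shape:
                raise InvalidParameterError("timestamps must match ear in length")

    @property
    def n_frames(self) -> int:
        return int(self.ear.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.ear).sum())

    @property
    def duration(self) -> float:
        """Recording length in seconds (frame count over frame rate)."""
        return self.n_frames / self.fps


@dataclass(frozen=True)
class EARSummary:
    """Whole-recording EAR statistics over non-missing frames."""

    average_ear: float
    max_ear: float
    min_ear: float
    n_frames: int
    n_missing: int

    def __post_init__(self) -> None:
        if not (self.min_ear <= self.average_ear <= self.max_ear):
            raise InvalidParameterError(
                "summary must satisfy min_ear <= average_ear <= max_ear"
            )
        if self.n_missing > self.n_frames:
            raise InvalidParameterError("n_missing cannot exceed n_frames")

    @property
    def span(self) -> float:
        """MaxEAR - MinEAR, the per-individual EAR range."""
        return self.max_ear - self.min_ear


def compute_ear(landmarks: EyeLandmarks) -> float:
    """Eye aspect ratio of a single eye.

    Raises
    ------
    GeometryError
        If the eye corners p1 and p4 coincide (zero horizontal width).
    """
    pts = landmarks.as_array()
    horizontal = float(np.linalg.norm(pts[0] - pts[3]))
    if horizontal == 0.0:
        raise GeometryError("degenerate eye geometry: p1 and p4 coincide")
    v1 = float(np.linalg.norm(pts[1] - pts[5]))  # ||p2 - p6||
    v2 = float(np.linalg.norm(pts[2] - pts[4]))  # ||p3 - p5||
    return (v1 + v2) / (2.0 * horizontal)


def combine_eyes(
    left_ear: float, right_ear: float, mode: EyeMode = "mean"
) -> float:
    """Combine per-eye EAR values into one per-frame value.

    ``mean`` (default) averages whichever eyes are available and falls back
    to the single available eye; both missing yields MISSING.  ``left`` and
    ``right`` select one eye unconditionally; ``min`` takes the smaller of
    the available values.
    """
    left_ok, right_ok = not is_missing(left_ear), not is_missing(right_ear)
    if mode == "left":
        return left_ear
    if mode == "right":
        return right_ear
    if mode == "mean":
        if left_ok and right_ok:
            return 0.5 * (left_ear + right_ear)
        return left_ear if left_ok else (right_ear if right_ok else MISSING)
    if mode == "min":
        if left_ok and right_ok:
            return min(left_ear, right_ear)
        return left_ear if left_ok else (right_ear if right_ok else MISSING)
    raise InvalidParameterError(f"unknown eye-combination mode {mode!r}")


def build_series(
    frames: Sequence[LandmarkFrame],
    mode: EyeMode = "mean",
    fps: float | None = None,
) -> EARSeries:
    """Turn ordered landmark frames into an EAR series, one entry per frame.

    Invalid frames (or frames with both eyes absent) become MISSING entries.
    When frames carry no explicit timestamps, ``fps`` is required and
    timestamps are derived as ``frame_index / fps``; when timestamps are
    present and ``fps`` is not given, the frame rate is inferred from them.
    """
    if len(frames) == 0:
        raise EmptyDataError("empty recording: no landmark frames")
    indices = [f.frame_index for f in frames]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise InvalidParameterError("frame_index must be strictly increasing")

    values = np.empty(len(frames))
    for i, frame in enumerate(frames):
        if not frame.valid or (frame.left is None and frame.right is None):
            values[i] = MISSING
            continue
        left = compute_ear(frame.left) if frame.left is not None else MISSING
        right = compute_ear(frame.right) if frame.right is not None else MISSING
        values[i] = combine_eyes(left, right, mode=mode)

    have_ts = all(f.timestamp is not None for f in frames)
    if have_ts:
        timestamps = np.array([f.timestamp for f in frames], dtype=float)
        if fps is None:
            if len(frames) < 2 or timestamps[-1] <= timestamps[0]:
                raise InvalidParameterError(
                    "cannot infer fps from timestamps; pass fps explicitly"
                )
            fps = (len(frames) - 1) / (timestamps[-1] - timestamps[0])
        return EARSeries(ear=values, fps=fps, timestamps=timestamps)
    if fps is None:
        raise InvalidParameterError("fps is required when frames lack timestamps")
    timestamps = np.array(indices, dtype=float) / fps
    return EARSeries(ear=values, fps=fps, timestamps=timestamps)


def summarize(
    series: EARSeries,
    robust: bool = False,
    percentiles: tuple[float, float] = (0.5, 99.5),
) -> EARSummary:
    """AverageEAR / MaxEAR / MinEAR over the non-missing frames.

    By default the extrema are the raw sample min and max over all processed
    frames.  ``robust=True`` replaces them with the given (lower, upper)
    percentiles to guard against single-frame glitches; this variant is off
    by default and not part of the validated pipeline.
    """
    values = series.ear[np.isfinite(series.ear)]
    if values.size == 0:
        raise EmptyDataError("no non-missing EAR values to summarize")
    mean = float(values.mean())
    if robust:
        lo, hi = np.percentile(values, percentiles)
        # heavy one-sided glitches can pull the mean outside the trimmed
        # range; widen so min <= average <= max always holds
        lo, hi = min(float(lo), mean), max(float(hi), mean)
    else:
        lo, hi = float(values.min()), float(values.max())
    # guard against float summation error pushing the mean past an extremum
    mean = min(max(mean, lo), hi)
    return EARSummary(
        average_ear=mean,
        max_ear=float(hi),
        min_ear=float(lo),
        n_frames=series.n_frames,
        n_missing=series.n_missing,
    )
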