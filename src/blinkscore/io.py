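"""Readers and writers for the package's plain-text dialects.

All files are UTF-8 CSV (comma-separated, header row, "." decimal) or JSON.

- Landmark CSV: ``frame,timestamp,eye,p1x,p1y,...,p6x,p6y,valid`` — one row
  per eye per frame; an invalid frame is a single row with ``valid`` false
  and empty coordinates.  Landmark JSON: an array of frame objects with
  ``frame``, ``timestamp``, ``valid`` and per-eye landmark lists.
- EAR CSV: ``frame,timestamp,ear`` with an empty cell for a missing frame.
- Events CSV: ``start_frame,end_frame,n_frames,min_ear,kind``.
- Questionnaire CSV/JSON: ``id,age,sex,dry_gritty,regular_contact_lens``.
- Cohort CSV: ``id,group,age,sex,full_rate,partial_rate,eye_score,duration``.

Any function mapping a video file to a list of LandmarkFrame (for example a
face-mesh detector adapter) can feed :func:`blinkscore.ear.build_series`;
this package deliberately stops at the landmark level.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord
from .detect import BlinkEvent, BlinkKind, BlinkMetrics, ThresholdPair
from .ear import EARSeries, EyeLandmarks, LandmarkFrame
from .exceptions import EmptyDataError, InvalidParameterError
from .scoring import EyeHealthReport, QuestionnaireRecord

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "read_landmark_json",
    "read_ear_csv",
    "write_ear_csv",
    "read_events_csv",
    "write_events_csv",
    "read_questionnaire",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_metrics_json",
    "write_report_json",
]

_COORD_COLS = [f"p{i}{axis}" for i in range(1, 7) for axis in ("x", "y")]


def _landmarks_from_row(row: pd.Series) -> EyeLandmarks:
    coords = [float(row[c]) for c in _COORD_COLS]
    points = [(coords[2 * i], coords[2 * i + 1]) for i in range(6)]
    return EyeLandmarks(*points)


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value)


def read_landmark_csv(path: str | Path) -> list[LandmarkFrame]:
    """Read one-row-per-eye landmark CSV into ordered LandmarkFrames."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "eye", "valid"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"landmark CSV {path} must have columns {sorted(required)}"
        )
    frames: list[LandmarkFrame] = []
    for frame_idx, rows in df.groupby("frame", sort=True):
        timestamp = None
        if "timestamp" in rows.columns and rows["timestamp"].notna().any():
            timestamp = float(rows["timestamp"].iloc[0])
        eyes: dict[str, EyeLandmarks] = {}
        valid = False
        for i, row in rows.iterrows():
            if not _truthy(row["valid"]):
                continue
            try:
                eyes[str(row["eye"]).strip().lower()] = _landmarks_from_row(row)
            except (ValueError, KeyError) as exc:
                raise InvalidParameterError(
                    f"malformed landmark row {i} (frame {frame_idx}): {exc}"
                ) from exc
            valid = True
        frames.append(
            LandmarkFrame(
                frame_index=int(frame_idx),
                timestamp=timestamp,
                left=eyes.get("left"),
                right=eyes.get("right"),
                valid=valid,
            )
        )
    if not frames:
        raise EmptyDataError(f"no landmark rows in {path}")
    return frames


def write_landmark_csv(frames: Sequence[LandmarkFrame], path: str | Path) -> None:
    rows = []
    for frame in frames:
        if not frame.valid:
            rows.append(
                {"frame": frame.frame_index, "timestamp": frame.timestamp,
                 "eye": "", "valid": False,
                 **{c: "" for c in _COORD_COLS}}
            )
            continue
        for eye_name, eye in (("left", frame.left), ("right", frame.right)):
            if eye is None:
                continue
            pts = eye.as_array()
            row = {"frame": frame.frame_index, "timestamp": frame.timestamp,
                   "eye": eye_name, "valid": True}
            for i in range(6):
                row[f"p{i + 1}x"], row[f"p{i + 1}y"] = pts[i]
            rows.append(row)
    columns = ["frame", "timestamp", "eye", *_COORD_COLS, "valid"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_landmark_json(path: str | Path) -> list[LandmarkFrame]:
    """Read the JSON landmark dialect (array of frame objects)."""
    data = json.loads(Path(path).read_text())
    frames = []
    for obj in data:
        eyes = {}
        for eye_name in ("left", "right"):
            pts = obj.get(eye_name)
            if pts:
                eyes[eye_name] = EyeLandmarks(*(tuple(p) for p in pts))
        frames.append(
            LandmarkFrame(
                frame_index=int(obj["frame"]),
                timestamp=obj.get("timestamp"),
                left=eyes.get("left"),
                right=eyes.get("right"),
                valid=bool(obj.get("valid", bool(eyes))),
            )
        )
    if not frames:
        raise EmptyDataError(f"no frames in {path}")
    return frames


def read_ear_csv(path: str | Path, fps: float | None = None) -> EARSeries:
    """Read an EAR CSV; empty ``ear`` cells become missing frames."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "ear" not in df.columns:
        raise InvalidParameterError(f"EAR CSV {path} must have an 'ear' column")
    if len(df) == 0:
        raise EmptyDataError(f"no EAR rows in {path}")
    ear = df["ear"].to_numpy(dtype=float)
    timestamps = None
    if "timestamp" in df.columns and df["timestamp"].notna().all():
        timestamps = df["timestamp"].to_numpy(dtype=float)
        if fps is None:
            if len(df) < 2 or timestamps[-1] <= timestamps[0]:
                raise InvalidParameterError(
                    "cannot infer fps from timestamps; pass fps explicitly"
                )
            fps = (len(df) - 1) / (timestamps[-1] - timestamps[0])
    if fps is None:
        raise InvalidParameterError("fps is required when the CSV has no timestamps")
    return EARSeries(ear=ear, fps=float(fps), timestamps=timestamps)


def _exact(x: float) -> str:
    """Shortest decimal that round-trips the float exactly; NaN -> empty."""
    return "" if np.isnan(x) else repr(float(x))


def write_ear_csv(series: EARSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "timestamp": [_exact(t) for t in series.timestamps],
            "ear": [_exact(v) for v in series.ear],
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[BlinkEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        BlinkEvent(
            start_frame=int(row["start_frame"]),
            end_frame=int(row["end_frame"]),
            min_ear=float(row["min_ear"]),
            kind=BlinkKind(str(row["kind"])),
        )
        for _, row in df.iterrows()
    ]


def write_events_csv(events: Sequence[BlinkEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "n_frames": e.n_frames,
                "min_ear": _exact(e.min_ear),
                "kind": e.kind.value,
            }
            for e in events
        ],
        columns=["start_frame", "end_frame", "n_frames", "min_ear", "kind"],
    ).to_csv(path, index=False)


_QUESTIONNAIRE_FIELDS = ("age", "sex", "dry_gritty", "regular_contact_lens")


def _questionnaire_from_mapping(data: dict, origin: str) -> QuestionnaireRecord:
    for name in _QUESTIONNAIRE_FIELDS:
        if name not in data or data[name] is None or (
            isinstance(data[name], float) and np.isnan(data[name])
        ):
            raise InvalidParameterError(
                f"questionnaire {origin} is missing required field '{name}'"
            )
    return QuestionnaireRecord(
        age=float(data["age"]),
        sex=str(data["sex"]).strip().upper(),
        dry_gritty=_truthy(data["dry_gritty"]),
        regular_contact_lens=_truthy(data["regular_contact_lens"]),
    )


def read_questionnaire(path: str | Path) -> list[tuple[str, QuestionnaireRecord]]:
    """Read questionnaire records as (id, record) pairs from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = [data]
        return [
            (str(obj.get("id", i)), _questionnaire_from_mapping(obj, f"record {i}"))
            for i, obj in enumerate(data)
        ]
    df = pd.read_csv(path)
    if len(df) == 0:
        raise EmptyDataError(f"no questionnaire rows in {path}")
    return [
        (str(row.get("id", i)), _questionnaire_from_mapping(dict(row), f"row {i}"))
        for i, row in df.iterrows()
    ]


def read_cohort_csv(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise EmptyDataError(f"no cohort rows in {path}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ParticipantRecord(
                    id=str(row["id"]),
                    group=str(row["group"]).strip().upper(),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().upper(),
                    full_rate_per_min=float(row["full_rate"]),
                    partial_rate_per_min=float(row["partial_rate"]),
                    eye_score=int(row["eye_score"]),
                    video_duration_s=float(row["duration"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InvalidParameterError(f"malformed cohort row {i}: {exc}") from exc
    return records


def write_cohort_csv(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "full_rate": r.full_rate_per_min,
                "partial_rate": r.partial_rate_per_min,
                "eye_score": r.eye_score,
                "duration": r.video_duration_s,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_metrics_json(
    metrics: BlinkMetrics,
    path: str | Path,
    thresholds: ThresholdPair | None = None,
    config: dict | None = None,
) -> None:
    """Metrics plus the thresholds and configuration that produced them."""
    payload = {
        "full_count": metrics.full_count,
        "partial_count": metrics.partial_count,
        "duration_s": metrics.duration,
        "full_rate_per_min": metrics.full_rate_per_min,
        "partial_rate_per_min": metrics.partial_rate_per_min,
        "open_close_ratio_pct": metrics.open_close_ratio_pct,
        "thresholds": None
        if thresholds is None
        else {"full": thresholds.full, "partial": thresholds.partial},
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def write_report_json(report: EyeHealthReport, path: str | Path,
                      config: dict | None = None) -> None:
    payload = {
        "breakdown": {
            "blink_points": report.breakdown.blink_points,
            "partial_points": report.breakdown.partial_points,
            "gritty_points": report.breakdown.gritty_points,
            "woman_over_50_points": report.breakdown.woman_over_50_points,
            "lens_points": report.breakdown.lens_points,
        },
        "total": report.total,
        "category": report.category.value,
        "alert": report.alert,
        "inputs": {
            "full_rate_per_min": report.full_rate_per_min,
            "partial_rate_per_min": report.partial_rate_per_min,
            "age": report.questionnaire.age,
            "sex": report.questionnaire.sex,
            "dry_gritty": report.questionnaire.dry_gritty,
            "regular_contact_lens": report.questionnaire.regular_contact_lens,
        },
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
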