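"""Run configuration serialized alongside every report for reproducibility."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .detect import DEFAULT_MIN_RUN, FIXED_EAR_THRESHOLD

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of the analysis pipeline, with their defaults.

    ``threshold_mode`` selects the fixed single-threshold rule or the
    personalized dual-threshold rule; ``reference`` selects whether raw EAR
    values or excursion depths from MinEAR are compared to the thresholds.
    """

    fps: float = 30.0
    eye_mode: str = "mean"
    min_run: int = DEFAULT_MIN_RUN
    threshold_mode: str = "dynamic"  # "fixed" | "dynamic"
    fixed_threshold: float = FIXED_EAR_THRESHOLD
    reference: str = "absolute"  # "absolute" | "offset"
    robust_summary: bool = False
    robust_percentiles: tuple[float, float] = (0.5, 99.5)
    bridge_gap: int = 0
    ttest_variant: str = "student"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "robust_percentiles" in kwargs:
            kwargs["robust_percentiles"] = tuple(kwargs["robust_percentiles"])
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
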