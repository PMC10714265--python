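"""Threshold and task-queue configuration.

Every cutoff the flag engine and window statistics use lives in one
structured config so a run is fully described by (bundle, config).
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class TaskRules(BaseModel):
    """Priority rules for the investigation task queue."""

    high_count: int = 10
    med_count: int = 3


class ThresholdConfig(BaseModel):
    """All numeric cutoffs used by the flag engine and window statistics.

    Comparisons against these thresholds are strict (``<`` / ``>``) except
    the short-average-interview z rule, which fires at ``<=``.
    """

    short_question_seconds: float = 3.0
    long_question_seconds: float = 420.0
    stem_visit_cutoff: int = 1
    nonstem_visit_cutoff: int = 3
    short_field_pct: float = 30.0
    short_interview_minutes: dict[str, float] = Field(
        default_factory=lambda: {"LONG": 47.0, "SHORT": 32.0}
    )
    long_interview_minutes: dict[str, float] = Field(
        default_factory=lambda: {"LONG": 188.0, "SHORT": 128.0}
    )
    # None -> flag when every administered stem is negative (and at least
    # min_administered_stems were administered); an integer N -> flag when
    # the number of negative stems exceeds N.
    negative_stem_count_cutoff: Optional[int] = None
    min_administered_stems: int = 10
    treatment_length_minutes: float = 30.0
    completes_zscore_cutoff: float = 2.0
    prevalence_z_cutoff: float = 1.5
    short_avg_interview_z_cutoff: float = -2.0
    window_days: int = 14
    # z-scores over interviewers with few completes in a window are noise;
    # windows truncated by the study end routinely have single-digit counts
    min_completes_per_window: int = 10
    pause_threshold_seconds: float = 420.0
    monitoring_min_minutes: float = 15.0
    task_rules: TaskRules = Field(default_factory=TaskRules)

    @field_validator(
        "short_question_seconds",
        "long_question_seconds",
        "short_field_pct",
        "treatment_length_minutes",
        "completes_zscore_cutoff",
        "prevalence_z_cutoff",
        "pause_threshold_seconds",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("threshold must be > 0")
        return v

    @field_validator("window_days")
    @classmethod
    def _window_days(cls, v: int) -> int:
        if v < 1:
            raise ValueError("window_days must be >= 1")
        return v

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data or {})
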