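"""Flag summaries, monitoring coverage, task queue, profiles and exports.

Percentages are computed from integer counts with exact decimal
arithmetic and rounded half-up at the declared precision (2 decimals by
default), so summary cells are reproducible from their raw counts.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

from . import intervals
from .config import TaskRules
from .types import (
    CallRecord,
    Flag,
    FlagLevel,
    FlagType,
    MetricRecord,
    WindowStat,
)


class DenominatorKind:
    COMPLETED_CASES = "COMPLETED_CASES"
    TOUCHED_CASES = "TOUCHED_CASES"


#: Which denominator each flag type is reported against: question-time
#: flags are scored against every touched case, the rest against
#: completed cases only.
DENOMINATOR_KIND: dict[FlagType, str] = {
    FlagType.SHORT_QUESTION_TIME: DenominatorKind.TOUCHED_CASES,
    FlagType.SHORT_STEM_QUESTION_TIME: DenominatorKind.TOUCHED_CASES,
    FlagType.LONG_QUESTION_TIME: DenominatorKind.TOUCHED_CASES,
    FlagType.LONG_TREATMENT: DenominatorKind.TOUCHED_CASES,
    FlagType.HIGH_COMPLETES: DenominatorKind.COMPLETED_CASES,
    FlagType.HIGH_PCT_SHORT_TIME: DenominatorKind.COMPLETED_CASES,
    FlagType.SHORT_INTERVIEW: DenominatorKind.COMPLETED_CASES,
    FlagType.LONG_INTERVIEW: DenominatorKind.COMPLETED_CASES,
    FlagType.SHORT_AVG_INTERVIEW: DenominatorKind.COMPLETED_CASES,
    FlagType.HIGH_NEGATIVE_STEMS: DenominatorKind.COMPLETED_CASES,
    FlagType.MULTI_FIELD_VISITS: DenominatorKind.COMPLETED_CASES,
    FlagType.MULTI_STEM_FIELD_VISITS: DenominatorKind.COMPLETED_CASES,
    FlagType.PREVALENCE_RATE: DenominatorKind.COMPLETED_CASES,
}

#: Flag categories used to route review work between teams.
FLAG_CATEGORIES: dict[FlagType, str] = {
    FlagType.SHORT_QUESTION_TIME: "duration",
    FlagType.SHORT_STEM_QUESTION_TIME: "duration",
    FlagType.LONG_QUESTION_TIME: "duration",
    FlagType.HIGH_PCT_SHORT_TIME: "duration",
    FlagType.SHORT_INTERVIEW: "duration",
    FlagType.LONG_INTERVIEW: "duration",
    FlagType.SHORT_AVG_INTERVIEW: "duration",
    FlagType.LONG_TREATMENT: "duration",
    FlagType.HIGH_NEGATIVE_STEMS: "cidi",
    FlagType.MULTI_FIELD_VISITS: "cidi",
    FlagType.MULTI_STEM_FIELD_VISITS: "cidi",
    FlagType.PREVALENCE_RATE: "cidi",
    FlagType.HIGH_COMPLETES: "operational",
}

SKILLS = (
    "probing",
    "objections_refusals",
    "persuasion",
    "typing_speed",
    "project_knowledge",
    "verbatim_reading",
)


def pct(numerator: int, denominator: int, digits: int = 2) -> float:
    """100*n/d rounded half-up at ``digits`` decimals, exact in decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-digits)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def round_half_up(value: float, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FlagSummaryRow:
    flag_type: FlagType
    n_flags: int
    pct_of_total_flags: float
    n_cases_flagged: int
    pct_of_denominator: float
    denominator_kind: str
    denominator_n: int


def flag_summary(
    flags: list[Flag],
    n_completed: int,
    n_touched: int,
    precision: int = 2,
) -> list[FlagSummaryRow]:
    """Per-type flag counts and shares (the fielded summary table shape).

    ``n_cases_flagged`` counts distinct case ids; window-level flags with
    no case id count distinct (interviewer, window) pairs instead.
    """
    if n_completed <= 0 or n_touched <= 0:
        raise ValueError("summary denominators must be positive")
    total = len(flags)
    by_type: dict[FlagType, list[Flag]] = {}
    for f in flags:
        by_type.setdefault(f.flag_type, []).append(f)

    rows = []
    for ftype in sorted(by_type, key=lambda t: t.value):
        fs = by_type[ftype]
        units = {
            f.case_id if f.case_id is not None else (f.interviewer_id, f.window) for f in fs
        }
        kind = DENOMINATOR_KIND[ftype]
        denom = n_touched if kind == DenominatorKind.TOUCHED_CASES else n_completed
        rows.append(
            FlagSummaryRow(
                flag_type=ftype,
                n_flags=len(fs),
                pct_of_total_flags=pct(len(fs), total, precision),
                n_cases_flagged=len(units),
                pct_of_denominator=pct(len(units), denom, precision),
                denominator_kind=kind,
                denominator_n=denom,
            )
        )
    return rows


def module_breakdown(
    flags: Iterable[Flag],
    module_of: dict[str, str],
    precision: int = 2,
) -> dict[str, tuple[int, float]]:
    """Share of flags per catalog module (n, pct of the given flags)."""
    fs = list(flags)
    counts: dict[str, int] = {}
    for f in fs:
        mod = module_of.get(f.question_id or "", "unknown")
        counts[mod] = counts.get(mod, 0) + 1
    return {
        mod: (n, pct(n, len(fs), precision)) for mod, n in sorted(counts.items())
    }


def visit_count_breakdown(
    flags: Iterable[Flag], precision: int = 2
) -> dict[int, tuple[int, float]]:
    """Share of multi-visit flags by observed visit count."""
    fs = list(flags)
    counts: dict[int, int] = {}
    for f in fs:
        k = int(f.observed_value)
        counts[k] = counts.get(k, 0) + 1
    return {k: (n, pct(n, len(fs), precision)) for k, n in sorted(counts.items())}


@dataclass
class CoverageReport:
    total_dial_hours: float
    monitored_hours: float
    pct_dial_time_monitored: float
    n_completed: int
    n_monitored_min: int
    pct_monitored_min: float
    n_any_monitoring: int
    pct_any_monitoring: float
    min_minutes: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def monitoring_coverage(
    call_records: Iterable[CallRecord],
    completed_case_ids: set[str],
    min_minutes: float = 15.0,
) -> CoverageReport:
    """Monitoring-load accounting over merged monitored intervals.

    Percentages of completed cases are half-up at 2 decimals; overlapping
    monitoring sessions on a case are merged before measuring.
    """
    per_case: dict[str, list[tuple[dt.datetime, dt.datetime]]] = {}
    dial_seconds = 0.0
    monitored_seconds = 0.0
    for c in call_records:
        dial_seconds += c.duration_seconds
        if c.monitored_intervals:
            per_case.setdefault(c.case_id, []).extend(c.monitored_intervals)

    n_min = 0
    n_any = 0
    for case_id, ivals in per_case.items():
        secs = intervals.total_seconds(ivals)
        monitored_seconds += secs
        if case_id in completed_case_ids:
            if secs > 0:
                n_any += 1
            if secs >= min_minutes * 60.0:
                n_min += 1

    n_completed = len(completed_case_ids)
    return CoverageReport(
        total_dial_hours=dial_seconds / 3600.0,
        monitored_hours=monitored_seconds / 3600.0,
        pct_dial_time_monitored=(
            round_half_up(100.0 * monitored_seconds / dial_seconds, 2) if dial_seconds else 0.0
        ),
        n_completed=n_completed,
        n_monitored_min=n_min,
        pct_monitored_min=pct(n_min, n_completed, 2) if n_completed else 0.0,
        n_any_monitoring=n_any,
        pct_any_monitoring=pct(n_any, n_completed, 2) if n_completed else 0.0,
        min_minutes=min_minutes,
    )


# ---------------------------------------------------------------------------
# investigation task queue


class TaskStatus:
    OPEN = "OPEN"
    ASSIGNED_MONITORING = "ASSIGNED_MONITORING"
    RESOLVED = "RESOLVED"


_TASK_TRANSITIONS = {
    TaskStatus.OPEN: {TaskStatus.ASSIGNED_MONITORING, TaskStatus.RESOLVED},
    TaskStatus.ASSIGNED_MONITORING: {TaskStatus.RESOLVED},
    TaskStatus.RESOLVED: set(),
}


@dataclass
class InvestigationTask:
    """One per-interviewer investigation work item for a review period."""

    task_id: str
    interviewer_id: str
    period: tuple[dt.date, dt.date]
    flag_ids: list[int]
    priority: str  # HIGH | MEDIUM | LOW
    status: str = TaskStatus.OPEN
    notes: list[tuple[str, str]] = field(default_factory=list)  # (iso timestamp, text)

    def add_note(self, text: str, at: Optional[dt.datetime] = None) -> None:
        ts = (at or dt.datetime.now(dt.timezone.utc)).isoformat()
        self.notes.append((ts, text))

    def advance(self, new_status: str, note: str = "", at: Optional[dt.datetime] = None) -> None:
        if new_status not in _TASK_TRANSITIONS[self.status]:
            raise ValueError(f"illegal task transition {self.status} -> {new_status}")
        self.status = new_status
        if note:
            self.add_note(note, at=at)

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "interviewer_id": self.interviewer_id,
            "period": [self.period[0].isoformat(), self.period[1].isoformat()],
            "flag_ids": list(self.flag_ids),
            "priority": self.priority,
            "status": self.status,
            "notes": [list(n) for n in self.notes],
        }


def build_task_queue(
    flags: list[Flag],
    period: tuple[dt.date, dt.date],
    rules: Optional[TaskRules] = None,
) -> list[InvestigationTask]:
    """One task per flagged interviewer; priority from flag gravity.

    HIGH when any window-level flag is present or the case-flag count
    reaches ``rules.high_count``; MEDIUM at ``rules.med_count``; else LOW.
    ``flag_ids`` index into the given flag list, sorted newest-first.
    """
    rules = rules or TaskRules()
    by_ivw: dict[str, list[int]] = {}
    for i, f in enumerate(flags):
        by_ivw.setdefault(f.interviewer_id, []).append(i)

    tasks = []
    for ivw in sorted(by_ivw):
        idxs = by_ivw[ivw]
        idxs.sort(
            key=lambda i: (flags[i].triggered_at or dt.date.min, i), reverse=True
        )
        window_level = any(flags[i].level is FlagLevel.INTERVIEWER_WINDOW for i in idxs)
        n_case = sum(1 for i in idxs if flags[i].level is FlagLevel.CASE)
        if window_level or n_case >= rules.high_count:
            priority = "HIGH"
        elif n_case >= rules.med_count:
            priority = "MEDIUM"
        else:
            priority = "LOW"
        tasks.append(
            InvestigationTask(
                task_id=f"task-{period[0].isoformat()}-{ivw}",
                interviewer_id=ivw,
                period=period,
                flag_ids=idxs,
                priority=priority,
            )
        )
    return tasks


# ---------------------------------------------------------------------------
# profiles and evaluations


@dataclass
class EvaluationRecord:
    """Supervisor skill scores (0..5) for one interviewer on one date."""

    interviewer_id: str
    date: dt.date
    scores: dict[str, int]

    def validate(self) -> None:
        if set(self.scores) != set(SKILLS):
            raise ValueError(f"scores must cover exactly the skills {SKILLS}")
        for skill, score in self.scores.items():
            if not 0 <= score <= 5:
                raise ValueError(f"score for {skill} out of range 0..5: {score}")


def interviewer_profile(
    interviewer_id: str,
    flags: list[Flag],
    metrics: list[MetricRecord],
    window_stats: list[WindowStat],
    known_interviewers: Optional[set[str]] = None,
    date_range: Optional[tuple[dt.date, dt.date]] = None,
    category: Optional[str] = None,
) -> dict:
    """Aggregated view of one interviewer: flag counts by type and
    category, metric values, and the z trajectory over windows."""
    if known_interviewers is not None and interviewer_id not in known_interviewers:
        raise KeyError(f"unknown interviewer {interviewer_id!r}")

    def in_range(day: Optional[dt.date]) -> bool:
        if date_range is None or day is None:
            return True
        return date_range[0] <= day < date_range[1]

    my_flags = [
        f
        for f in flags
        if f.interviewer_id == interviewer_id
        and in_range(f.triggered_at)
        and (category is None or FLAG_CATEGORIES[f.flag_type] == category)
    ]
    by_type = {t.value: 0 for t in FlagType}
    by_category = {"duration": 0, "cidi": 0, "operational": 0}
    for f in my_flags:
        by_type[f.flag_type.value] += 1
        by_category[FLAG_CATEGORIES[f.flag_type]] += 1

    my_metrics = [
        {
            "metric": m.metric.value,
            "period": [m.period[0].isoformat(), m.period[1].isoformat()],
            "case_id": m.case_id,
            "value": m.value,
        }
        for m in metrics
        if m.interviewer_id == interviewer_id and m.case_id is None
    ]
    trajectory = [
        {
            "window": [s.window[0].isoformat(), s.window[1].isoformat()],
            "statistic": s.statistic.value,
            "n_cases": s.n_cases,
            "value": s.value,
            "z": s.z,
        }
        for s in window_stats
        if s.interviewer_id == interviewer_id
    ]
    return {
        "interviewer_id": interviewer_id,
        "n_flags": len(my_flags),
        "flags_by_type": by_type,
        "flags_by_category": by_category,
        "metrics": my_metrics,
        "window_trajectory": trajectory,
    }


# ---------------------------------------------------------------------------
# exports


def _fmt_window(w: Optional[tuple[dt.date, dt.date]]) -> str:
    return f"{w[0].isoformat()}|{w[1].isoformat()}" if w else ""


def write_flags_csv(flags: list[Flag], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "flag_type", "level", "interviewer_id", "case_id", "question_id",
                "window", "observed_value", "threshold_value", "triggered_at",
                "status", "notes",
            ]
        )
        for f in flags:
            w.writerow(
                [
                    f.flag_type.value,
                    f.level.value,
                    f.interviewer_id,
                    f.case_id or "",
                    f.question_id or "",
                    _fmt_window(f.window),
                    repr(float(f.observed_value)),
                    repr(float(f.threshold_value)),
                    f.triggered_at.isoformat() if f.triggered_at else "",
                    f.status.value,
                    f.notes,
                ]
            )
    return path


def write_summary_csv(rows: list[FlagSummaryRow], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "flag_type", "n_flags", "pct_of_total_flags", "n_cases_flagged",
                "pct_of_denominator", "denominator_kind", "denominator_n",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    r.flag_type.value, r.n_flags, f"{r.pct_of_total_flags:.2f}",
                    r.n_cases_flagged, f"{r.pct_of_denominator:.2f}",
                    r.denominator_kind, r.denominator_n,
                ]
            )
    return path


def write_metrics_csv(metrics: list[MetricRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["interviewer_id", "metric", "period_start", "period_end", "case_id", "value"])
        for m in metrics:
            value = m.value if isinstance(m.value, bool) else repr(float(m.value))
            w.writerow(
                [
                    m.interviewer_id, m.metric.value, m.period[0].isoformat(),
                    m.period[1].isoformat(), m.case_id or "", value,
                ]
            )
    return path


def write_window_stats_csv(stats: list[WindowStat], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["interviewer_id", "window_start", "window_end", "statistic", "n_cases", "value", "z"]
        )
        for s in stats:
            w.writerow(
                [
                    s.interviewer_id, s.window[0].isoformat(), s.window[1].isoformat(),
                    s.statistic.value, s.n_cases, repr(float(s.value)),
                    "" if s.z is None else repr(float(s.z)),
                ]
            )
    return path


def write_json(data: dict | list, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    return path
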