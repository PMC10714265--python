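"""End-to-end orchestration: bundle -> visits -> flags -> reports."""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from . import flag_engine, reporting, session_builder, window_stats
from .config import ThresholdConfig
from .types import (
    Activity,
    Disposition,
    FieldVisit,
    Flag,
    InterviewTimeline,
    MetricRecord,
    ParadataBundle,
    WindowStat,
)


@dataclass
class PipelineResult:
    visits: list[FieldVisit]
    timelines: dict[str, InterviewTimeline]
    flags: list[Flag]
    window_stats: list[WindowStat]
    metrics: list[MetricRecord]
    day_stats: list[flag_engine.DayStat]
    issues: list[str] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self._completed_ids)

    _completed_ids: set[str] = field(default_factory=set)
    _touched_ids: set[str] = field(default_factory=set)

    @property
    def n_touched(self) -> int:
        return len(self._touched_ids)


def day_stats_from_bundle(bundle: ParadataBundle) -> list[flag_engine.DayStat]:
    """Interviewer-day completes and logged calling hours."""
    completes: dict[tuple[str, dt.date], int] = {}
    for c in bundle.case_records:
        if c.disposition is Disposition.COMPLETE:
            key = (c.interviewer_id, c.call_start.date())
            completes[key] = completes.get(key, 0) + 1

    hours: dict[tuple[str, dt.date], float] = {}
    for t in bundle.time_logs:
        if t.activity is not Activity.CALLING:
            continue
        key = (t.interviewer_id, t.start.date())
        hours[key] = hours.get(key, 0.0) + t.duration_seconds / 3600.0

    keys = sorted(set(completes) | set(hours))
    return [
        flag_engine.DayStat(
            interviewer_id=ivw,
            day=day,
            completes=completes.get((ivw, day), 0),
            calling_hours=hours.get((ivw, day), 0.0),
        )
        for ivw, day in keys
    ]


def run_pipeline(
    bundle: ParadataBundle,
    cfg: Optional[ThresholdConfig] = None,
    compute_metrics: bool = True,
) -> PipelineResult:
    """Run the whole QC engine over one bundle."""
    cfg = cfg or ThresholdConfig()
    catalog = bundle.catalog

    visits = session_builder.build_field_visits(bundle.audit_events, catalog)
    timelines = session_builder.build_timelines(
        bundle.audit_events, catalog, cfg.pause_threshold_seconds
    )

    visits_by_case: dict[str, list] = {}
    for v in visits:
        visits_by_case.setdefault(v.case_id, []).append(v)

    case_meta = {
        c.case_id: (c.interviewer_id, c.call_end.date()) for c in bundle.case_records
    }

    flags: list[Flag] = []
    issues: list[str] = []

    flags.extend(flag_engine.flag_question_times(visits, catalog, cfg))
    counts = session_builder.count_question_visits(visits)
    flags.extend(flag_engine.flag_multiple_visits(counts, catalog, cfg, case_meta))
    for c in bundle.case_records:
        flags.extend(
            flag_engine.flag_case_profile(
                c, timelines.get(c.case_id), visits_by_case.get(c.case_id, []), catalog, cfg
            )
        )

    day_stats = day_stats_from_bundle(bundle)
    flags.extend(flag_engine.flag_high_completes(day_stats, cfg, issues))

    start = bundle.study_start_date
    stats = window_stats.prevalence_stat(bundle.case_records, start, cfg.window_days)
    stats += window_stats.mean_interview_stat(
        bundle.case_records, timelines, start, cfg.window_days
    )
    stats_z = window_stats.window_zscores(stats, cfg)
    flags.extend(window_stats.emit_window_flags(stats_z, cfg))

    metrics: list[MetricRecord] = []
    if compute_metrics:
        all_dates = [c.call_start.date() for c in bundle.case_records]
        if all_dates:
            period = (min(all_dates), max(all_dates) + dt.timedelta(days=1))
            metrics = window_stats.compute_metrics(bundle, visits, timelines, period)

    result = PipelineResult(
        visits=visits,
        timelines=timelines,
        flags=flags,
        window_stats=stats_z,
        metrics=metrics,
        day_stats=day_stats,
        issues=issues,
    )
    result._completed_ids = {
        c.case_id for c in bundle.case_records if c.disposition is Disposition.COMPLETE
    }
    result._touched_ids = {c.case_id for c in bundle.case_records}
    return result


def export_reports(
    bundle: ParadataBundle,
    result: PipelineResult,
    out_dir,
    cfg: Optional[ThresholdConfig] = None,
) -> None:
    """Write the standard report set (CSV/JSON) for one pipeline run."""
    from pathlib import Path

    cfg = cfg or ThresholdConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reporting.write_flags_csv(result.flags, out / "flags.csv")
    if result.flags and result.n_completed and result.n_touched:
        rows = reporting.flag_summary(result.flags, result.n_completed, result.n_touched)
        reporting.write_summary_csv(rows, out / "summary.csv")
    reporting.write_metrics_csv(result.metrics, out / "metrics.csv")
    reporting.write_window_stats_csv(result.window_stats, out / "window_stats.csv")

    coverage = reporting.monitoring_coverage(
        bundle.call_records, result._completed_ids, cfg.monitoring_min_minutes
    )
    reporting.write_json(coverage.to_dict(), out / "coverage.json")

    all_dates = [c.call_start.date() for c in bundle.case_records]
    if all_dates:
        period = (min(all_dates), max(all_dates) + dt.timedelta(days=1))
        tasks = reporting.build_task_queue(result.flags, period, cfg.task_rules)
        reporting.write_json([t.to_dict() for t in tasks], out / "tasks.json")

    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    roster = set(bundle.interviewer_ids())
    for ivw in sorted(roster):
        profile = reporting.interviewer_profile(
            ivw, result.flags, result.metrics, result.window_stats, known_interviewers=roster
        )
        reporting.write_json(profile, profiles_dir / f"{ivw}.json")

    # session exports share the bundle dialect rules
    _write_visits_csv(result, out / "visits.csv")
    _write_timelines_csv(result, out / "timelines.csv")


def _write_visits_csv(result: PipelineResult, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "case_id", "interviewer_id", "question_id", "visit_index", "enter",
                "exit", "field_time_seconds", "value_changed", "synthetic_exit",
            ]
        )
        for v in result.visits:
            w.writerow(
                [
                    v.case_id, v.interviewer_id, v.question_id, v.visit_index,
                    v.enter.isoformat(), v.exit.isoformat(),
                    repr(float(v.field_time_seconds)),
                    "true" if v.value_changed else "false",
                    "true" if v.synthetic_exit else "false",
                ]
            )


def _write_timelines_csv(result: PipelineResult, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "case_id", "interviewer_id", "total_survey_seconds",
                "adjusted_total_seconds", "treatment_seconds", "timeout_bug",
            ]
        )
        for case_id in sorted(result.timelines):
            tl = result.timelines[case_id]
            w.writerow(
                [
                    tl.case_id, tl.interviewer_id,
                    repr(float(tl.total_survey_seconds)),
                    repr(float(tl.adjusted_total_seconds)),
                    repr(float(tl.treatment_seconds)),
                    "true" if tl.timeout_bug else "false",
                ]
            )
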