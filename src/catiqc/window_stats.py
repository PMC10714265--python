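"""Interviewer x window statistics, cross-interviewer z-scores, the two
windowed flags, and the verification metrics.

Windows are tumbling (aligned to the study start date), ``window_days``
long, half-open on dates. Standardization within a window uses the sample
standard deviation over interviewers with at least
``min_completes_per_window`` completed cases; z is null when fewer than
two interviewers are eligible or the spread is zero.
"""
from __future__ import annotations

import datetime as dt
import math
from typing import Iterable, Mapping, Optional

from . import intervals
from .config import ThresholdConfig
from .types import (
    CaseRecord,
    Disposition,
    FieldVisit,
    Flag,
    FlagLevel,
    FlagType,
    InterviewTimeline,
    Metric,
    MetricRecord,
    ParadataBundle,
    Activity,
    Statistic,
    WindowStat,
)

Window = tuple[dt.date, dt.date]


def partition_windows(
    study_start_date: dt.date,
    dates: Iterable[dt.date],
    window_days: int = 14,
) -> list[Window]:
    """Consecutive half-open windows covering every date, aligned to start."""
    dates = list(dates)
    if not dates:
        return []
    lo, hi = min(dates), max(dates)
    if lo < study_start_date:
        raise ValueError(
            f"date {lo.isoformat()} precedes study start {study_start_date.isoformat()}"
        )
    width = dt.timedelta(days=window_days)
    windows: list[Window] = []
    start = study_start_date
    while start <= hi:
        windows.append((start, start + width))
        start += width
    return windows


def window_of(day: dt.date, study_start_date: dt.date, window_days: int = 14) -> Window:
    """The tumbling window containing ``day`` (boundary dates open the later
    window, per half-open semantics)."""
    idx = (day - study_start_date).days // window_days
    if idx < 0:
        raise ValueError(f"date {day.isoformat()} precedes study start")
    start = study_start_date + dt.timedelta(days=idx * window_days)
    return (start, start + dt.timedelta(days=window_days))


def prevalence_stat(
    cases: Iterable[CaseRecord],
    study_start_date: dt.date,
    window_days: int = 14,
) -> list[WindowStat]:
    """Per interviewer x window share of completed cases with any disorder."""
    acc: dict[tuple[str, Window], list[bool]] = {}
    for c in cases:
        if c.disposition is not Disposition.COMPLETE:
            continue
        if c.any_disorder is None:
            raise ValueError(f"case {c.case_id}: COMPLETE case lacks any_disorder")
        w = window_of(c.call_start.date(), study_start_date, window_days)
        acc.setdefault((c.interviewer_id, w), []).append(c.any_disorder)
    return [
        WindowStat(
            interviewer_id=ivw,
            window=w,
            statistic=Statistic.PREVALENCE,
            n_cases=len(vals),
            value=sum(vals) / len(vals),
        )
        for (ivw, w), vals in sorted(acc.items())
    ]


def mean_interview_stat(
    cases: Iterable[CaseRecord],
    timelines: Mapping[str, InterviewTimeline],
    study_start_date: dt.date,
    window_days: int = 14,
) -> list[WindowStat]:
    """Per interviewer x window mean adjusted interview length in minutes."""
    acc: dict[tuple[str, Window], list[float]] = {}
    for c in cases:
        if c.disposition is not Disposition.COMPLETE:
            continue
        tl = timelines.get(c.case_id)
        if tl is None:
            continue
        w = window_of(c.call_start.date(), study_start_date, window_days)
        acc.setdefault((c.interviewer_id, w), []).append(tl.adjusted_total_seconds / 60.0)
    return [
        WindowStat(
            interviewer_id=ivw,
            window=w,
            statistic=Statistic.MEAN_INTERVIEW_MINUTES,
            n_cases=len(vals),
            value=sum(vals) / len(vals),
        )
        for (ivw, w), vals in sorted(acc.items())
    ]


def window_zscores(stats: list[WindowStat], cfg: ThresholdConfig) -> list[WindowStat]:
    """Attach cross-interviewer z-scores within each (window, statistic).

    Eligible interviewers are those with ``n_cases >= min_completes_per_window``;
    ineligible interviewers (and all interviewers when SD is zero or fewer
    than two are eligible) keep ``z = None``. Input is not mutated.
    """
    groups: dict[tuple[Window, Statistic], list[WindowStat]] = {}
    for s in stats:
        groups.setdefault((s.window, s.statistic), []).append(s)

    out: list[WindowStat] = []
    for (window, statistic), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        eligible = [s for s in members if s.n_cases >= cfg.min_completes_per_window]
        z_by_id: dict[str, Optional[float]] = {s.interviewer_id: None for s in members}
        if len(eligible) >= 2:
            vals = [s.value for s in eligible]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            sd = math.sqrt(var)
            # guard float fuzz: equal values must yield null z, not +/-inf
            if sd > 1e-12 * max(1.0, abs(mean)):
                for s in eligible:
                    z_by_id[s.interviewer_id] = (s.value - mean) / sd
        for s in members:
            out.append(
                WindowStat(
                    interviewer_id=s.interviewer_id,
                    window=window,
                    statistic=statistic,
                    n_cases=s.n_cases,
                    value=s.value,
                    z=z_by_id[s.interviewer_id],
                )
            )
    return out


def emit_window_flags(stats_with_z: list[WindowStat], cfg: ThresholdConfig) -> list[Flag]:
    """Windowed flags from standardized statistics.

    Prevalence flags on ``|z| > prevalence_z_cutoff`` (sign preserved in
    the observed value); short-average-interview flags on
    ``z <= short_avg_interview_z_cutoff``.
    """
    flags: list[Flag] = []
    for s in stats_with_z:
        if s.z is None:
            continue
        if s.statistic is Statistic.PREVALENCE and abs(s.z) > cfg.prevalence_z_cutoff:
            flags.append(
                Flag(
                    flag_type=FlagType.PREVALENCE_RATE,
                    level=FlagLevel.INTERVIEWER_WINDOW,
                    interviewer_id=s.interviewer_id,
                    observed_value=s.z,
                    threshold_value=cfg.prevalence_z_cutoff,
                    window=s.window,
                    triggered_at=s.window[1],
                    notes=f"prevalence={s.value:.4f} n={s.n_cases}",
                )
            )
        elif (
            s.statistic is Statistic.MEAN_INTERVIEW_MINUTES
            and s.z <= cfg.short_avg_interview_z_cutoff
        ):
            flags.append(
                Flag(
                    flag_type=FlagType.SHORT_AVG_INTERVIEW,
                    level=FlagLevel.INTERVIEWER_WINDOW,
                    interviewer_id=s.interviewer_id,
                    observed_value=s.z,
                    threshold_value=cfg.short_avg_interview_z_cutoff,
                    window=s.window,
                    triggered_at=s.window[1],
                    notes=f"mean_minutes={s.value:.2f} n={s.n_cases}",
                )
            )
    return flags


def _hours(seconds: float) -> float:
    return seconds / 3600.0


def compute_metrics(
    bundle: ParadataBundle,
    visits: list[FieldVisit],
    timelines: Mapping[str, InterviewTimeline],
    period: tuple[dt.date, dt.date],
) -> list[MetricRecord]:
    """Verification metrics per interviewer (and per case) over a period.

    Units: *_TIME per interviewer in hours, monitoring times in minutes,
    per-case survey times in minutes, after-call work in seconds,
    ADT section length in seconds, rates per hour.
    """
    p_start = dt.datetime.combine(period[0], dt.time.min, tzinfo=dt.timezone.utc)
    p_end = dt.datetime.combine(period[1], dt.time.min, tzinfo=dt.timezone.utc)

    def in_period(ts: dt.datetime) -> bool:
        return p_start <= ts < p_end

    calls = [c for c in bundle.call_records if in_period(c.start)]
    cases = [c for c in bundle.case_records if in_period(c.call_start)]
    logs = [t for t in bundle.time_logs if t.start < p_end and t.end > p_start]
    pvisits = [v for v in visits if in_period(v.enter)]

    ivws = sorted(
        {c.interviewer_id for c in calls}
        | {c.interviewer_id for c in cases}
        | {t.interviewer_id for t in logs}
    )

    out: list[MetricRecord] = []
    for ivw in ivws:
        my_calls = sorted(
            (c for c in calls if c.interviewer_id == ivw), key=lambda c: (c.start, c.call_id)
        )
        my_cases = [c for c in cases if c.interviewer_id == ivw]
        my_logs = [t for t in logs if t.interviewer_id == ivw]
        my_visits = [v for v in pvisits if v.interviewer_id == ivw]

        calling_blocks = intervals.clip(
            [(t.start, t.end) for t in my_logs if t.activity is Activity.CALLING],
            p_start,
            p_end,
        )
        calling_hours = _hours(intervals.total_seconds(calling_blocks))
        scheduled_hours = _hours(
            intervals.total_seconds(
                intervals.clip([(t.start, t.end) for t in my_logs], p_start, p_end)
            )
        )

        cisco_hours = _hours(sum(c.duration_seconds for c in my_calls))
        dials = len(my_calls)
        completes = sum(1 for c in my_cases if c.disposition is Disposition.COMPLETE)

        # after-call work: gap to the next dial within the same calling block
        gaps: list[float] = []
        for a, b in zip(my_calls, my_calls[1:]):
            if b.start < a.end:
                continue
            same_block = any(
                blk_a <= a.end and b.start <= blk_b for blk_a, blk_b in calling_blocks
            )
            if same_block:
                gaps.append((b.start - a.end).total_seconds())

        observed = intervals.merge(
            [(c.start, c.end) for c in my_calls]
            + [(v.enter, v.exit) for v in my_visits if v.exit > v.enter]
        )
        observed_hours = _hours(intervals.total_seconds(observed))

        monitored_minutes_total = 0.0
        for c in my_calls:
            merged = intervals.merge(c.monitored_intervals)
            mins = intervals.total_seconds(merged) / 60.0
            monitored_minutes_total += mins
            if mins > 0:
                out.append(
                    MetricRecord(ivw, Metric.MONITORING_TIME_PER_CASE, period, mins, c.case_id)
                )

        def add(metric: Metric, value: float | bool, case_id: Optional[str] = None) -> None:
            out.append(MetricRecord(ivw, metric, period, value, case_id))

        add(Metric.CISCO_CALLING_TIME, cisco_hours)
        add(Metric.DIALS_PER_HOUR, dials / calling_hours if calling_hours > 0 else 0.0)
        add(
            Metric.COMPLETES_PER_HOUR,
            completes / scheduled_hours if scheduled_hours > 0 else 0.0,
        )
        add(
            Metric.ADJ_COMPLETES_PER_HOUR,
            completes / calling_hours if calling_hours > 0 else 0.0,
        )
        add(Metric.AVG_AFTER_CALL_WORK_TIME, sum(gaps) / len(gaps) if gaps else 0.0)
        add(Metric.REPORTED_TIME_DISCREPANCY, calling_hours - observed_hours)
        add(Metric.MONITORING_TIME_PER_INTERVIEWER, monitored_minutes_total)
        add(Metric.MONITORED, monitored_minutes_total > 0)

        for c in sorted(my_cases, key=lambda c: c.case_id):
            tl = timelines.get(c.case_id)
            if tl is None:
                continue
            add(Metric.BLAISE_SURVEY_TIME, tl.total_survey_seconds / 60.0, c.case_id)
            add(Metric.BLAISE_ADJUSTED_TOTAL_TIME, tl.adjusted_total_seconds / 60.0, c.case_id)
            add(Metric.BLAISE_TREATMENT_TIME, tl.treatment_seconds / 60.0, c.case_id)
            add(
                Metric.ADT_SECTION_LENGTH,
                sum(tl.per_module_seconds.values()),
                c.case_id,
            )
            add(Metric.TIMEOUT_BUG, tl.timeout_bug, c.case_id)

    return out
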