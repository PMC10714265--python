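"""Case-level quality flags computed from visits, timelines and case records.

All threshold comparisons are strict (``<`` / ``>``); boundary values do
not flag. Interviewer-day completes are flagged on the exposure-adjusted
rate (completes per logged calling hour), standardized across all
interviewer-days of the same calendar day — raw complete counts are never
flagged directly.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .config import ThresholdConfig
from .types import (
    CaseRecord,
    Disposition,
    FieldVisit,
    Flag,
    FlagLevel,
    FlagType,
    InterviewTimeline,
    QuestionCatalogEntry,
    StemAnswer,
)


@dataclass
class DayStat:
    """Completes and logged calling exposure for one interviewer-day."""

    interviewer_id: str
    day: dt.date
    completes: int
    calling_hours: float


#: Which engine operation is responsible for each of the 13 flag types.
FLAG_SOURCES: dict[FlagType, str] = {
    FlagType.SHORT_QUESTION_TIME: "flag_engine.flag_question_times",
    FlagType.SHORT_STEM_QUESTION_TIME: "flag_engine.flag_question_times",
    FlagType.LONG_QUESTION_TIME: "flag_engine.flag_question_times",
    FlagType.MULTI_FIELD_VISITS: "flag_engine.flag_multiple_visits",
    FlagType.MULTI_STEM_FIELD_VISITS: "flag_engine.flag_multiple_visits",
    FlagType.HIGH_PCT_SHORT_TIME: "flag_engine.flag_case_profile",
    FlagType.SHORT_INTERVIEW: "flag_engine.flag_case_profile",
    FlagType.LONG_INTERVIEW: "flag_engine.flag_case_profile",
    FlagType.HIGH_NEGATIVE_STEMS: "flag_engine.flag_case_profile",
    FlagType.LONG_TREATMENT: "flag_engine.flag_case_profile",
    FlagType.HIGH_COMPLETES: "flag_engine.flag_high_completes",
    FlagType.PREVALENCE_RATE: "window_stats.emit_window_flags",
    FlagType.SHORT_AVG_INTERVIEW: "window_stats.emit_window_flags",
}


def flag_question_times(
    visits: Iterable[FieldVisit],
    catalog: list[QuestionCatalogEntry],
    cfg: ThresholdConfig,
) -> list[Flag]:
    """Per-visit short/long question-time flags.

    Short flags honour the catalog exclusion list (questions that read in
    under the cutoff by design are never flagged); the long flag applies
    to every question.
    """
    by_id = {q.question_id: q for q in catalog}
    flags: list[Flag] = []
    for v in visits:
        entry = by_id.get(v.question_id)
        is_stem = entry.is_stem if entry else False
        excluded = entry.exclude_from_short_flag if entry else False
        if v.field_time_seconds < cfg.short_question_seconds and not excluded:
            flags.append(
                Flag(
                    flag_type=(
                        FlagType.SHORT_STEM_QUESTION_TIME
                        if is_stem
                        else FlagType.SHORT_QUESTION_TIME
                    ),
                    level=FlagLevel.CASE,
                    interviewer_id=v.interviewer_id,
                    case_id=v.case_id,
                    question_id=v.question_id,
                    observed_value=v.field_time_seconds,
                    threshold_value=cfg.short_question_seconds,
                    triggered_at=v.exit.date(),
                )
            )
        if v.field_time_seconds > cfg.long_question_seconds:
            flags.append(
                Flag(
                    flag_type=FlagType.LONG_QUESTION_TIME,
                    level=FlagLevel.CASE,
                    interviewer_id=v.interviewer_id,
                    case_id=v.case_id,
                    question_id=v.question_id,
                    observed_value=v.field_time_seconds,
                    threshold_value=cfg.long_question_seconds,
                    triggered_at=v.exit.date(),
                )
            )
    return flags


def flag_multiple_visits(
    visit_counts: Mapping[tuple[str, str], int],
    catalog: list[QuestionCatalogEntry],
    cfg: ThresholdConfig,
    case_meta: Optional[Mapping[str, tuple[str, dt.date]]] = None,
) -> list[Flag]:
    """Multi-visit flags from per-(case, question) visit counts.

    ``case_meta`` maps case_id -> (interviewer_id, date) so flags carry
    attribution; counts for questions absent from the catalog raise,
    because their stem status is unknown.
    """
    by_id = {q.question_id: q for q in catalog}
    case_meta = case_meta or {}
    flags: list[Flag] = []
    for (case_id, question_id), count in sorted(visit_counts.items()):
        entry = by_id.get(question_id)
        if entry is None:
            raise KeyError(f"question {question_id!r} not in catalog; stem status unknown")
        ivw, day = case_meta.get(case_id, ("", None))
        if entry.is_stem and count > cfg.stem_visit_cutoff:
            ftype, cutoff = FlagType.MULTI_STEM_FIELD_VISITS, cfg.stem_visit_cutoff
        elif not entry.is_stem and count > cfg.nonstem_visit_cutoff:
            ftype, cutoff = FlagType.MULTI_FIELD_VISITS, cfg.nonstem_visit_cutoff
        else:
            continue
        flags.append(
            Flag(
                flag_type=ftype,
                level=FlagLevel.CASE,
                interviewer_id=ivw,
                case_id=case_id,
                question_id=question_id,
                observed_value=float(count),
                threshold_value=float(cutoff),
                triggered_at=day,
            )
        )
    return flags


def short_time_fraction(
    visits: Iterable[FieldVisit],
    catalog: list[QuestionCatalogEntry],
    cfg: ThresholdConfig,
) -> Optional[float]:
    """Percent of short-eligible visits under the short cutoff; None if no
    eligible visits (the flag is then recorded as skipped, not evaluated)."""
    by_id = {q.question_id: q for q in catalog}
    eligible = 0
    short = 0
    for v in visits:
        entry = by_id.get(v.question_id)
        if entry is None or entry.exclude_from_short_flag:
            continue
        eligible += 1
        if v.field_time_seconds < cfg.short_question_seconds:
            short += 1
    if eligible == 0:
        return None
    return 100.0 * short / eligible


def flag_case_profile(
    case: CaseRecord,
    timeline: Optional[InterviewTimeline],
    visits: list[FieldVisit],
    catalog: list[QuestionCatalogEntry],
    cfg: ThresholdConfig,
) -> list[Flag]:
    """Whole-case flags: short-time percentage, interview length, negative
    stems and treatment length.

    Length/stem/percentage flags are evaluated only for completed cases;
    the treatment-length flag applies to any case with a timeline.
    """
    flags: list[Flag] = []
    day = case.call_end.date()

    if timeline is not None and timeline.treatment_seconds > cfg.treatment_length_minutes * 60:
        flags.append(
            Flag(
                flag_type=FlagType.LONG_TREATMENT,
                level=FlagLevel.CASE,
                interviewer_id=case.interviewer_id,
                case_id=case.case_id,
                observed_value=timeline.treatment_seconds / 60.0,
                threshold_value=cfg.treatment_length_minutes,
                triggered_at=day,
            )
        )

    if case.disposition is not Disposition.COMPLETE:
        return flags

    pct = short_time_fraction(visits, catalog, cfg)
    if pct is not None and pct > cfg.short_field_pct:
        flags.append(
            Flag(
                flag_type=FlagType.HIGH_PCT_SHORT_TIME,
                level=FlagLevel.CASE,
                interviewer_id=case.interviewer_id,
                case_id=case.case_id,
                observed_value=pct,
                threshold_value=cfg.short_field_pct,
                triggered_at=day,
            )
        )

    if timeline is not None:
        minutes = timeline.adjusted_total_seconds / 60.0
        short_cut = cfg.short_interview_minutes[case.version.value]
        long_cut = cfg.long_interview_minutes[case.version.value]
        if minutes < short_cut:
            flags.append(
                Flag(
                    flag_type=FlagType.SHORT_INTERVIEW,
                    level=FlagLevel.CASE,
                    interviewer_id=case.interviewer_id,
                    case_id=case.case_id,
                    observed_value=minutes,
                    threshold_value=short_cut,
                    triggered_at=day,
                )
            )
        if minutes > long_cut:
            flags.append(
                Flag(
                    flag_type=FlagType.LONG_INTERVIEW,
                    level=FlagLevel.CASE,
                    interviewer_id=case.interviewer_id,
                    case_id=case.case_id,
                    observed_value=minutes,
                    threshold_value=long_cut,
                    triggered_at=day,
                )
            )

    administered = [a for a in case.stem_answers.values() if a is not StemAnswer.MISSING]
    negatives = sum(1 for a in administered if a is StemAnswer.NEGATIVE)
    if cfg.negative_stem_count_cutoff is None:
        hit = (
            len(administered) >= cfg.min_administered_stems
            and negatives == len(administered)
            and negatives > 0
        )
        threshold = float(len(administered))
    else:
        hit = negatives > cfg.negative_stem_count_cutoff
        threshold = float(cfg.negative_stem_count_cutoff)
    if hit:
        flags.append(
            Flag(
                flag_type=FlagType.HIGH_NEGATIVE_STEMS,
                level=FlagLevel.CASE,
                interviewer_id=case.interviewer_id,
                case_id=case.case_id,
                observed_value=float(negatives),
                threshold_value=threshold,
                triggered_at=day,
            )
        )
    return flags


def flag_high_completes(
    day_stats: Iterable[DayStat],
    cfg: ThresholdConfig,
    issues: Optional[list[str]] = None,
) -> list[Flag]:
    """High-completes flags on the exposure-adjusted completion rate.

    For each calendar day, rates (completes / logged calling hours) are
    standardized across all interviewer-days with positive exposure; an
    interviewer-day flags when its z-score reaches the configured cutoff.
    Interviewer-days with completes but zero logged hours are recorded as
    data inconsistencies and excluded.
    """
    by_day: dict[dt.date, list[DayStat]] = {}
    for s in day_stats:
        if s.calling_hours <= 0:
            if s.completes > 0 and issues is not None:
                issues.append(
                    f"{s.interviewer_id} {s.day.isoformat()}: "
                    f"{s.completes} completes with zero logged calling hours"
                )
            continue
        by_day.setdefault(s.day, []).append(s)

    flags: list[Flag] = []
    for day in sorted(by_day):
        stats = by_day[day]
        if len(stats) < 2:
            continue
        rates = [s.completes / s.calling_hours for s in stats]
        mean = sum(rates) / len(rates)
        var = sum((r - mean) ** 2 for r in rates) / (len(rates) - 1)
        sd = math.sqrt(var)
        if sd == 0:
            continue
        for s, rate in zip(stats, rates):
            z = (rate - mean) / sd
            if z >= cfg.completes_zscore_cutoff:
                flags.append(
                    Flag(
                        flag_type=FlagType.HIGH_COMPLETES,
                        level=FlagLevel.INTERVIEWER_WINDOW,
                        interviewer_id=s.interviewer_id,
                        observed_value=z,
                        threshold_value=cfg.completes_zscore_cutoff,
                        window=(day, day + dt.timedelta(days=1)),
                        triggered_at=day,
                        notes=f"rate={rate:.4f}/h completes={s.completes} "
                        f"hours={s.calling_hours:.2f}",
                    )
                )
    return flags
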