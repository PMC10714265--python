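"""Reconstruct field visits and interview timelines from raw audit events.

Question fields are modal in the interviewing client: at most one field is
open at a time. A second ENTER (same or different question) therefore
implies a lost EXIT; the open visit is closed at the new ENTER's timestamp
and marked ``synthetic_exit``. EXIT events with no open visit for that
question are discarded and counted as orphans; ENTERs are never dropped.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from . import intervals
from .types import AuditEvent, EventKind, FieldVisit, InterviewTimeline, QuestionCatalogEntry

UNKNOWN_MODULE = "unknown"


@dataclass
class VisitReconstruction:
    """Visits plus accounting of irregular events, per event log."""

    visits: list[FieldVisit] = field(default_factory=list)
    orphan_exits: int = 0
    synthetic_exits: int = 0
    stray_value_sets: int = 0


class NoTimelineError(Exception):
    """Raised when a case has no audit events to build a timeline from."""


def reconstruct_visits(events: list[AuditEvent]) -> VisitReconstruction:
    """Pair ENTER/EXIT events into visits for one or more cases.

    Events are consumed in log order (the audit trail is append-ordered;
    the bundle dialect stores it timestamp-sorted). A clock glitch that
    yields an EXIT timestamp before its ENTER therefore surfaces as a
    negative-duration visit, which the timeline marks as a timeout bug.
    """
    by_case: dict[str, list[AuditEvent]] = {}
    for e in events:
        by_case.setdefault(e.case_id, []).append(e)

    result = VisitReconstruction()
    for case_id in sorted(by_case):
        _reconstruct_case(by_case[case_id], result)

    # deterministic global order: by case then enter time then index
    result.visits.sort(key=lambda v: (v.case_id, v.enter, v.question_id, v.visit_index))
    return result


def _reconstruct_case(events: list[AuditEvent], result: VisitReconstruction) -> None:
    open_q: str | None = None
    open_enter: dt.datetime | None = None
    open_ivw = ""
    value_changed = False
    indices: dict[str, int] = {}
    visits: list[FieldVisit] = []

    def close(at: dt.datetime, synthetic: bool) -> None:
        nonlocal open_q, open_enter, value_changed
        assert open_q is not None and open_enter is not None
        idx = indices.get(open_q, 0) + 1
        indices[open_q] = idx
        visits.append(
            FieldVisit(
                case_id=events[0].case_id,
                interviewer_id=open_ivw,
                question_id=open_q,
                visit_index=idx,
                enter=open_enter,
                exit=at,
                field_time_seconds=(at - open_enter).total_seconds(),
                value_changed=value_changed,
                synthetic_exit=synthetic,
            )
        )
        if synthetic:
            result.synthetic_exits += 1
        open_q = None
        open_enter = None
        value_changed = False

    for e in events:
        if e.kind is EventKind.ENTER:
            if open_q is not None:
                close(e.timestamp, synthetic=True)
            open_q = e.question_id
            open_enter = e.timestamp
            open_ivw = e.interviewer_id
            value_changed = False
        elif e.kind is EventKind.EXIT:
            if open_q is not None and open_q == e.question_id:
                close(e.timestamp, synthetic=False)
            else:
                result.orphan_exits += 1
        elif e.kind is EventKind.VALUE_SET:
            if open_q is not None and open_q == e.question_id:
                value_changed = True
            else:
                result.stray_value_sets += 1
        # KEYSTROKE events carry no visit semantics

    if open_q is not None:
        close(events[-1].timestamp, synthetic=True)

    result.visits.extend(visits)


def build_field_visits(
    events: list[AuditEvent],
    catalog: list[QuestionCatalogEntry] | None = None,
) -> list[FieldVisit]:
    """Reconstructed visits ordered by (case, enter time)."""
    return reconstruct_visits(events).visits


def count_question_visits(visits: list[FieldVisit]) -> dict[tuple[str, str], int]:
    """Max visit_index per (case_id, question_id); conserves total visits."""
    counts: dict[tuple[str, str], int] = {}
    for v in visits:
        key = (v.case_id, v.question_id)
        if v.visit_index > counts.get(key, 0):
            counts[key] = v.visit_index
    return counts


def build_timeline(
    events: list[AuditEvent],
    catalog: list[QuestionCatalogEntry],
    pause_threshold_seconds: float = 420.0,
) -> InterviewTimeline:
    """Session timing summary for one case.

    ``total_survey_seconds`` spans first ENTER to last EXIT; the adjusted
    total excises every between-visit gap strictly longer than
    ``pause_threshold_seconds``. Per-module seconds sum field times by
    catalog module (unknown questions fall into ``"unknown"``).
    """
    if not events:
        raise NoTimelineError("no timeline: case has zero audit events")
    case_ids = {e.case_id for e in events}
    if len(case_ids) != 1:
        raise ValueError(f"build_timeline expects one case, got {sorted(case_ids)}")

    rec = reconstruct_visits(events)
    visits = rec.visits
    if not visits:
        raise NoTimelineError("no timeline: no reconstructable visits")

    first_enter = min(v.enter for v in visits)
    last_exit = max(v.exit for v in visits)
    total = (last_exit - first_enter).total_seconds()

    spans = [(v.enter, v.exit) for v in visits if v.exit > v.enter]
    excised = sum(
        (b - a).total_seconds()
        for a, b in intervals.gaps(spans)
        if (b - a).total_seconds() > pause_threshold_seconds
    )
    adjusted = total - excised

    module_of = {q.question_id: q.module for q in catalog}
    per_module: dict[str, float] = {}
    for v in visits:
        mod = module_of.get(v.question_id, UNKNOWN_MODULE)
        per_module[mod] = per_module.get(mod, 0.0) + v.field_time_seconds

    timeout_bug = any(
        v.field_time_seconds < 0 or v.field_time_seconds > total for v in visits
    )

    return InterviewTimeline(
        case_id=events[0].case_id,
        interviewer_id=visits[0].interviewer_id,
        total_survey_seconds=total,
        adjusted_total_seconds=adjusted,
        treatment_seconds=per_module.get("treatment", 0.0),
        per_module_seconds=per_module,
        timeout_bug=timeout_bug,
        first_enter=first_enter,
        last_exit=last_exit,
    )


def build_timelines(
    events: list[AuditEvent],
    catalog: list[QuestionCatalogEntry],
    pause_threshold_seconds: float = 420.0,
) -> dict[str, InterviewTimeline]:
    """Timelines for every case present in the event stream."""
    by_case: dict[str, list[AuditEvent]] = {}
    for e in events:
        by_case.setdefault(e.case_id, []).append(e)
    return {
        case_id: build_timeline(case_events, catalog, pause_threshold_seconds)
        for case_id, case_events in sorted(by_case.items())
    }
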