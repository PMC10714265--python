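"""Core record types shared across the QC engine.

All timestamps are timezone-aware and normalized to UTC; all intervals are
half-open ``[start, end)`` and durations are ``end - start`` in seconds.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

UTC = dt.timezone.utc


def ensure_utc(ts: dt.datetime) -> dt.datetime:
    """Normalize a timezone-aware datetime to UTC; reject naive datetimes."""
    if ts.tzinfo is UTC:
        return ts
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ValueError(f"naive datetime not allowed: {ts!r}")
    return ts.astimezone(UTC)


def parse_instant(text: str) -> dt.datetime:
    """Parse an ISO-8601 instant with explicit offset, normalized to UTC."""
    ts = dt.datetime.fromisoformat(text)
    return ensure_utc(ts)


class EventKind(str, Enum):
    ENTER = "ENTER"
    EXIT = "EXIT"
    KEYSTROKE = "KEYSTROKE"
    VALUE_SET = "VALUE_SET"


class Activity(str, Enum):
    CALLING = "CALLING"
    SHIFT_PREP = "SHIFT_PREP"
    TECH_SUPPORT = "TECH_SUPPORT"
    BREAK = "BREAK"


class Version(str, Enum):
    LONG = "LONG"
    SHORT = "SHORT"


class Disposition(str, Enum):
    COMPLETE = "COMPLETE"
    PARTIAL = "PARTIAL"
    REFUSAL = "REFUSAL"
    NONCONTACT = "NONCONTACT"
    OTHER = "OTHER"


class StemAnswer(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    MISSING = "MISSING"


class Gender(str, Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    UNKNOWN = "UNKNOWN"


class FlagType(str, Enum):
    HIGH_COMPLETES = "HIGH_COMPLETES"
    SHORT_QUESTION_TIME = "SHORT_QUESTION_TIME"
    SHORT_STEM_QUESTION_TIME = "SHORT_STEM_QUESTION_TIME"
    HIGH_PCT_SHORT_TIME = "HIGH_PCT_SHORT_TIME"
    SHORT_INTERVIEW = "SHORT_INTERVIEW"
    LONG_INTERVIEW = "LONG_INTERVIEW"
    SHORT_AVG_INTERVIEW = "SHORT_AVG_INTERVIEW"
    HIGH_NEGATIVE_STEMS = "HIGH_NEGATIVE_STEMS"
    MULTI_FIELD_VISITS = "MULTI_FIELD_VISITS"
    MULTI_STEM_FIELD_VISITS = "MULTI_STEM_FIELD_VISITS"
    PREVALENCE_RATE = "PREVALENCE_RATE"
    LONG_QUESTION_TIME = "LONG_QUESTION_TIME"
    LONG_TREATMENT = "LONG_TREATMENT"


class FlagLevel(str, Enum):
    CASE = "CASE"
    INTERVIEWER_WINDOW = "INTERVIEWER_WINDOW"


class FlagStatus(str, Enum):
    OPEN = "OPEN"
    INVESTIGATING = "INVESTIGATING"
    RESOLVED = "RESOLVED"


class Statistic(str, Enum):
    PREVALENCE = "PREVALENCE"
    MEAN_INTERVIEW_MINUTES = "MEAN_INTERVIEW_MINUTES"


class Metric(str, Enum):
    MONITORED = "MONITORED"
    MONITORING_TIME_PER_CASE = "MONITORING_TIME_PER_CASE"
    MONITORING_TIME_PER_INTERVIEWER = "MONITORING_TIME_PER_INTERVIEWER"
    BLAISE_SURVEY_TIME = "BLAISE_SURVEY_TIME"
    BLAISE_ADJUSTED_TOTAL_TIME = "BLAISE_ADJUSTED_TOTAL_TIME"
    BLAISE_TREATMENT_TIME = "BLAISE_TREATMENT_TIME"
    CISCO_CALLING_TIME = "CISCO_CALLING_TIME"
    AVG_AFTER_CALL_WORK_TIME = "AVG_AFTER_CALL_WORK_TIME"
    DIALS_PER_HOUR = "DIALS_PER_HOUR"
    COMPLETES_PER_HOUR = "COMPLETES_PER_HOUR"
    ADJ_COMPLETES_PER_HOUR = "ADJ_COMPLETES_PER_HOUR"
    REPORTED_TIME_DISCREPANCY = "REPORTED_TIME_DISCREPANCY"
    ADT_SECTION_LENGTH = "ADT_SECTION_LENGTH"
    TIMEOUT_BUG = "TIMEOUT_BUG"


@dataclass
class AuditEvent:
    """One keystroke/field-entry/field-exit record from the audit trail."""

    event_id: str
    case_id: str
    interviewer_id: str
    session_id: str
    question_id: str
    kind: EventKind
    timestamp: dt.datetime
    value: Optional[str] = None

    def __post_init__(self) -> None:
        self.timestamp = ensure_utc(self.timestamp)
        if type(self.kind) is not EventKind:
            self.kind = EventKind(self.kind)

    def validate(self) -> None:
        if self.kind is EventKind.VALUE_SET and self.value is None:
            raise ValueError(f"VALUE_SET event {self.event_id} carries no value")
        if self.kind in (EventKind.ENTER, EventKind.EXIT) and self.value is not None:
            raise ValueError(f"{self.kind.value} event {self.event_id} must not carry a value")


@dataclass
class CallRecord:
    """One outgoing dial with any live-monitoring sessions that overlapped it."""

    call_id: str
    interviewer_id: str
    case_id: str
    start: dt.datetime
    end: dt.datetime
    monitored_intervals: list[tuple[dt.datetime, dt.datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start = ensure_utc(self.start)
        self.end = ensure_utc(self.end)
        self.monitored_intervals = [
            (ensure_utc(a), ensure_utc(b)) for a, b in self.monitored_intervals
        ]

    def validate(self) -> None:
        if self.end < self.start:
            raise ValueError(f"call {self.call_id}: end < start")
        for a, b in self.monitored_intervals:
            if b < a:
                raise ValueError(f"call {self.call_id}: monitored interval end < start")
            if a < self.start or b > self.end:
                raise ValueError(f"call {self.call_id}: monitored interval outside call")

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class TimeLogEntry:
    """One self-reported activity block from the interviewer time tracker."""

    interviewer_id: str
    activity: Activity
    start: dt.datetime
    end: dt.datetime

    def __post_init__(self) -> None:
        self.start = ensure_utc(self.start)
        self.end = ensure_utc(self.end)
        if type(self.activity) is not Activity:
            self.activity = Activity(self.activity)

    def validate(self) -> None:
        if self.end < self.start:
            raise ValueError(f"time log for {self.interviewer_id}: end < start")

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class CaseRecord:
    """One case attempt's response-side record (disposition, stems, disorder)."""

    case_id: str
    interviewer_id: str
    version: Version
    call_start: dt.datetime
    call_end: dt.datetime
    disposition: Disposition
    respondent_gender: Optional[Gender] = None
    stem_answers: dict[str, StemAnswer] = field(default_factory=dict)
    any_disorder: Optional[bool] = None
    attempt_number: int = 1

    def __post_init__(self) -> None:
        self.call_start = ensure_utc(self.call_start)
        self.call_end = ensure_utc(self.call_end)
        if type(self.version) is not Version:
            self.version = Version(self.version)
        if type(self.disposition) is not Disposition:
            self.disposition = Disposition(self.disposition)
        if self.respondent_gender is not None and type(self.respondent_gender) is not Gender:
            self.respondent_gender = Gender(self.respondent_gender)
        if any(type(a) is not StemAnswer for a in self.stem_answers.values()):
            self.stem_answers = {q: StemAnswer(a) for q, a in self.stem_answers.items()}

    def validate(self) -> None:
        if self.call_end < self.call_start:
            raise ValueError(f"case {self.case_id}: call_end < call_start")
        if self.attempt_number < 1:
            raise ValueError(f"case {self.case_id}: attempt_number must be positive")
        if self.disposition is Disposition.COMPLETE and self.any_disorder is None:
            raise ValueError(f"case {self.case_id}: COMPLETE case lacks any_disorder")


@dataclass
class QuestionCatalogEntry:
    question_id: str
    module: str
    is_stem: bool
    baseline_read_seconds: float
    exclude_from_short_flag: bool = False

    def validate(self) -> None:
        if self.baseline_read_seconds < 0:
            raise ValueError(f"question {self.question_id}: negative baseline")


@dataclass
class ParadataBundle:
    """Container for the four paradata streams plus the question catalog."""

    audit_events: list[AuditEvent] = field(default_factory=list)
    call_records: list[CallRecord] = field(default_factory=list)
    time_logs: list[TimeLogEntry] = field(default_factory=list)
    case_records: list[CaseRecord] = field(default_factory=list)
    catalog: list[QuestionCatalogEntry] = field(default_factory=list)
    study_start_date: dt.date = dt.date(2021, 1, 20)
    provenance: dict = field(default_factory=dict)

    def catalog_by_id(self) -> dict[str, QuestionCatalogEntry]:
        return {q.question_id: q for q in self.catalog}

    def interviewer_ids(self) -> list[str]:
        ids: set[str] = set()
        ids.update(c.interviewer_id for c in self.case_records)
        ids.update(c.interviewer_id for c in self.call_records)
        ids.update(t.interviewer_id for t in self.time_logs)
        ids.update(e.interviewer_id for e in self.audit_events)
        return sorted(ids)


@dataclass
class FieldVisit:
    """A reconstructed contiguous stay in one question field."""

    case_id: str
    interviewer_id: str
    question_id: str
    visit_index: int
    enter: dt.datetime
    exit: dt.datetime
    field_time_seconds: float
    value_changed: bool = False
    synthetic_exit: bool = False


@dataclass
class InterviewTimeline:
    """Per-case session timing summary derived from the audit trail."""

    case_id: str
    interviewer_id: str
    total_survey_seconds: float
    adjusted_total_seconds: float
    treatment_seconds: float
    per_module_seconds: dict[str, float]
    timeout_bug: bool
    first_enter: dt.datetime
    last_exit: dt.datetime


@dataclass
class Flag:
    """One triggered quality indicator."""

    flag_type: FlagType
    level: FlagLevel
    interviewer_id: str
    observed_value: float
    threshold_value: float
    case_id: Optional[str] = None
    question_id: Optional[str] = None
    window: Optional[tuple[dt.date, dt.date]] = None
    triggered_at: Optional[dt.date] = None
    status: FlagStatus = FlagStatus.OPEN
    notes: str = ""

    def validate(self) -> None:
        if self.level is FlagLevel.CASE and self.case_id is None:
            raise ValueError(f"CASE-level flag {self.flag_type.value} lacks case_id")
        if self.level is FlagLevel.INTERVIEWER_WINDOW and self.window is None:
            raise ValueError(f"window-level flag {self.flag_type.value} lacks window")


@dataclass
class WindowStat:
    """An interviewer x window statistic with its cross-interviewer z-score."""

    interviewer_id: str
    window: tuple[dt.date, dt.date]
    statistic: Statistic
    n_cases: int
    value: float
    z: Optional[float] = None


@dataclass
class MetricRecord:
    """One verification-metric value for an interviewer (or case) and period."""

    interviewer_id: str
    metric: Metric
    period: tuple[dt.date, dt.date]
    value: float | bool
    case_id: Optional[str] = None
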