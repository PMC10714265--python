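"""Seeded synthetic paradata generator with interviewer archetypes.

Generates mutually consistent audit events, call records, time logs and
case records for a configurable roster of interviewers, so every flag and
metric has positive and negative test instances without any real data.

Determinism: each interviewer draws from an independent stream derived
from ``(seed, interviewer index)``, so re-generating with a different
archetype for one interviewer perturbs only that interviewer's rows.

Question read times are log-normal (sigma on the log scale configurable)
around catalog baselines scaled by the archetype; per-question baselines
are solved from the target mean interview lengths, so changing the
targets recalibrates the catalog. VALUE_SET events are emitted for stem
questions (answer content for other items is out of scope).
"""
from __future__ import annotations

import datetime as dt
import math
from bisect import bisect_right
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .types import (
    Activity,
    AuditEvent,
    CallRecord,
    CaseRecord,
    Disposition,
    EventKind,
    Gender,
    ParadataBundle,
    QuestionCatalogEntry,
    StemAnswer,
    TimeLogEntry,
    Version,
    UTC,
)

LOGNORMAL_SIGMA = 0.4
_LN_MEAN_FACTOR = math.exp(LOGNORMAL_SIGMA**2 / 2)


class ArchetypeConfig(BaseModel):
    """Behavior model for one interviewer archetype."""

    name: str
    question_time_scale: float = 1.0
    stem_positive_prob_scale: float = 1.0
    extra_revisit_prob: float = 0.0
    pause_rate_per_interview: float = 0.3
    long_pause_prob: float = 0.05
    overreport_hours: float = 0.0

    @field_validator("question_time_scale", "stem_positive_prob_scale")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("scales must be > 0")
        return v

    @field_validator("extra_revisit_prob", "pause_rate_per_interview", "long_pause_prob")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v


ARCHETYPES: dict[str, ArchetypeConfig] = {
    "COMPLIANT": ArchetypeConfig(name="COMPLIANT"),
    "SPEEDER": ArchetypeConfig(name="SPEEDER", question_time_scale=0.3),
    "FABRICATOR": ArchetypeConfig(
        name="FABRICATOR", stem_positive_prob_scale=0.1, overreport_hours=1.0
    ),
    "REVISITER": ArchetypeConfig(name="REVISITER", extra_revisit_prob=0.4),
    "SLOWPOKE": ArchetypeConfig(name="SLOWPOKE", question_time_scale=1.8),
}


class SimConfig(BaseModel):
    """Full simulation scenario."""

    n_interviewers: int = 20
    n_days: int = 14
    start_date: dt.date = dt.date(2021, 1, 20)
    shifts: list[tuple[int, int]] = Field(default_factory=lambda: [(9, 15), (15, 21)])
    archetype_assignment: dict[str, str] = Field(default_factory=dict)
    version_mix: float = 0.5  # share of LONG interviews
    mean_interview_minutes: dict[str, float] = Field(
        default_factory=lambda: {"LONG": 94.0, "SHORT": 64.0}
    )
    n_core_questions: int = 10
    prevalence_mean: float = 0.43
    prevalence_between_sd: float = 0.05
    disposition_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "COMPLETE": 0.08,
            "REFUSAL": 0.12,
            "NONCONTACT": 0.70,
            "PARTIAL": 0.05,
            "OTHER": 0.05,
        }
    )
    monitoring_rate: float = 0.15
    base_revisit_prob: float = 0.03
    stem_missing_prob: float = 0.02
    seed: int = 0

    @field_validator("n_interviewers")
    @classmethod
    def _n_ivw(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_interviewers must be >= 1")
        return v

    @field_validator("version_mix", "monitoring_rate", "base_revisit_prob", "stem_missing_prob")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v

    @field_validator("disposition_probs")
    @classmethod
    def _disp(cls, v: dict[str, float]) -> dict[str, float]:
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("disposition probabilities must sum to 1")
        for k in v:
            Disposition(k)
        return v

    def interviewer_ids(self) -> list[str]:
        return [f"I{i:02d}" for i in range(1, self.n_interviewers + 1)]

    def archetype_of(self, interviewer_id: str) -> ArchetypeConfig:
        name = self.archetype_assignment.get(interviewer_id, "COMPLIANT")
        return ARCHETYPES[name]


class InfeasibleConfigError(Exception):
    """Raised when interviews cannot fit inside the configured shifts."""


SHORT_MODULES = (
    "intro",
    "depression",
    "worry_anxiety",
    "stressful_experiences",
    "health",
    "covid",
    "treatment",
)


def make_catalog(sim: SimConfig) -> list[QuestionCatalogEntry]:
    """Question catalog with baselines solved from the target mean lengths.

    The SHORT version administers every module except ``core``; the LONG
    version adds ``core``. Fast items (baseline 8 s) live in health/covid;
    intro items read in ~2 s by design and are excluded from short-time
    flagging.
    """
    long_target = sim.mean_interview_minutes["LONG"] * 60.0
    short_target = sim.mean_interview_minutes["SHORT"] * 60.0
    if short_target > long_target:
        raise InfeasibleConfigError("SHORT interviews longer than LONG")

    entries: list[QuestionCatalogEntry] = []

    def add(qid: str, module: str, stem: bool, baseline: float, exclude: bool = False) -> None:
        entries.append(QuestionCatalogEntry(qid, module, stem, round(baseline, 4), exclude))

    for i in range(1, 5):
        add(f"intro_{i}", "intro", False, 2.0, exclude=True)

    stem_spec = [("depression", 2), ("worry_anxiety", 2), ("stressful_experiences", 3)]
    for module, n in stem_spec:
        for i in range(1, n + 1):
            add(f"{module}_stem_{i}", module, True, 12.0)

    for module, n in [("health", 6), ("covid", 6)]:
        for i in range(1, n + 1):
            add(f"{module}_q{i}", module, False, 8.0)

    for i in range(1, 6):
        add(f"treatment_q{i}", "treatment", False, 60.0)

    fixed_short = 4 * 2.0 + 7 * 12.0 + 12 * 8.0 + 5 * 60.0
    slow_spec = [("depression", 5), ("worry_anxiety", 4), ("stressful_experiences", 5)]
    n_slow = sum(n for _, n in slow_spec)
    slow_baseline = (short_target / _LN_MEAN_FACTOR - fixed_short) / n_slow
    if slow_baseline <= 0:
        raise InfeasibleConfigError(
            f"SHORT target {short_target}s too small for the fixed catalog items"
        )
    for module, n in slow_spec:
        for i in range(1, n + 1):
            add(f"{module}_q{i}", module, False, slow_baseline)

    if sim.n_core_questions > 0:
        core_baseline = (long_target - short_target) / _LN_MEAN_FACTOR / sim.n_core_questions
        if core_baseline <= 0:
            raise InfeasibleConfigError("LONG/SHORT targets leave no room for core module")
        for i in range(1, sim.n_core_questions + 1):
            add(f"core_q{i}", "core", False, core_baseline)

    return entries


def _question_plan(
    catalog: list[QuestionCatalogEntry], version: Version
) -> list[QuestionCatalogEntry]:
    if version is Version.LONG:
        return list(catalog)
    return [q for q in catalog if q.module in SHORT_MODULES]


class _InterviewerSim:
    """Generates one interviewer's rows on an isolated random stream."""

    def __init__(self, sim: SimConfig, idx: int, catalog: list[QuestionCatalogEntry]):
        self.sim = sim
        self.idx = idx
        self.interviewer_id = sim.interviewer_ids()[idx - 1]
        self.archetype = sim.archetype_of(self.interviewer_id)
        self.catalog = catalog
        self.rng = np.random.default_rng(np.random.SeedSequence([sim.seed, idx]))
        self.n_stems = sum(1 for q in catalog if q.is_stem)
        self._event_counter = 0

        # per-interviewer disorder propensity, calibrated to the target
        # cross-interviewer prevalence distribution
        q_i = float(
            np.clip(
                self.rng.normal(sim.prevalence_mean, sim.prevalence_between_sd), 0.02, 0.95
            )
        )
        p = 1.0 - (1.0 - q_i) ** (1.0 / self.n_stems)
        self.stem_positive_prob = min(1.0, p * self.archetype.stem_positive_prob_scale)

        self.shift = sim.shifts[(idx - 1) % len(sim.shifts)]

        # precomputed per-version question plans and log-scale read-time means
        self._plans = {
            v: _question_plan(catalog, v) for v in (Version.LONG, Version.SHORT)
        }
        self._mu = {
            v: np.log(
                np.array([q.baseline_read_seconds for q in plan])
                * self.archetype.question_time_scale
            )
            for v, plan in self._plans.items()
        }
        self._disp_names = sorted(sim.disposition_probs)
        self._disp_cum = list(
            np.cumsum([sim.disposition_probs[k] for k in self._disp_names])
        )

        self.audit_events: list[AuditEvent] = []
        self.call_records: list[CallRecord] = []
        self.time_logs: list[TimeLogEntry] = []
        self.case_records: list[CaseRecord] = []

    # -- helpers ---------------------------------------------------------

    def _next_event_id(self) -> str:
        self._event_counter += 1
        return f"{self.interviewer_id}-e{self._event_counter:07d}"

    def _emit(
        self,
        case_id: str,
        session_id: str,
        question_id: str,
        kind: EventKind,
        ts: dt.datetime,
        value: Optional[str] = None,
    ) -> None:
        self.audit_events.append(
            AuditEvent(
                event_id=self._next_event_id(),
                case_id=case_id,
                interviewer_id=self.interviewer_id,
                session_id=session_id,
                question_id=question_id,
                kind=kind,
                timestamp=ts,
                value=value,
            )
        )

    # -- interview -------------------------------------------------------

    def _run_interview(
        self,
        case_id: str,
        start: dt.datetime,
        version: Version,
        partial_fraction: Optional[float],
    ) -> tuple[dt.datetime, dict[str, StemAnswer], Optional[bool]]:
        """Emit audit events for one interview; returns (end, stems, disorder)."""
        plan = self._plans[version]
        mu = self._mu[version]
        if partial_fraction is not None:
            n_admin = max(1, int(len(plan) * partial_fraction))
            plan = plan[:n_admin]
            mu = mu[:n_admin]

        rng = self.rng
        arch = self.archetype
        sim = self.sim
        n = len(plan)
        session_id = f"{case_id}-s1"
        t = start
        stem_answers: dict[str, StemAnswer] = {}

        pause_here = -1
        if n > 1 and rng.random() < arch.pause_rate_per_interview:
            pause_here = int(rng.integers(1, n))
        long_pause_here = -1
        if rng.random() < arch.long_pause_prob:
            long_pause_here = int(rng.integers(0, n))

        durs = rng.lognormal(mu, LOGNORMAL_SIGMA)
        u_missing = rng.random(n)
        u_positive = rng.random(n)
        u_revisit = rng.random(n)
        emit = self._emit
        second = dt.timedelta(seconds=1)

        for qi, q in enumerate(plan):
            if qi == pause_here:  # between-visit break (excisable gap)
                t += (60.0 + 240.0 * rng.random()) * second

            dur = float(durs[qi])
            if qi == long_pause_here:  # respondent break inside the field
                dur += 480.0 + 420.0 * rng.random()

            enter = t
            t = enter + dur * second
            emit(case_id, session_id, q.question_id, EventKind.ENTER, enter)
            if q.is_stem:
                if u_missing[qi] < sim.stem_missing_prob:
                    answer = StemAnswer.MISSING
                else:
                    answer = (
                        StemAnswer.POSITIVE
                        if u_positive[qi] < self.stem_positive_prob
                        else StemAnswer.NEGATIVE
                    )
                stem_answers[q.question_id] = answer
                if answer is not StemAnswer.MISSING:
                    emit(
                        case_id,
                        session_id,
                        q.question_id,
                        EventKind.VALUE_SET,
                        enter + (dur * 0.8) * second,
                        value=answer.value,
                    )
            emit(case_id, session_id, q.question_id, EventKind.EXIT, t)

            revisit_p = sim.base_revisit_prob + (
                arch.extra_revisit_prob if q.is_stem else 0.0
            )
            if u_revisit[qi] < revisit_p:
                rdur = 3.5 + 4.5 * rng.random()
                renter = t
                t = renter + rdur * second
                emit(case_id, session_id, q.question_id, EventKind.ENTER, renter)
                if q.is_stem and q.question_id in stem_answers:
                    emit(
                        case_id,
                        session_id,
                        q.question_id,
                        EventKind.VALUE_SET,
                        renter + (rdur * 0.5) * second,
                        value=stem_answers[q.question_id].value,
                    )
                emit(case_id, session_id, q.question_id, EventKind.EXIT, t)

        if partial_fraction is not None:
            return t, stem_answers, None
        any_disorder = any(a is StemAnswer.POSITIVE for a in stem_answers.values())
        return t, stem_answers, any_disorder

    # -- day loop --------------------------------------------------------

    def run_day(self, day: dt.date) -> None:
        sim = self.sim
        rng = self.rng
        arch = self.archetype
        shift_start = dt.datetime.combine(day, dt.time(self.shift[0]), tzinfo=UTC)
        shift_end = dt.datetime.combine(day, dt.time(self.shift[1]), tzinfo=UTC)

        log_end = shift_end + dt.timedelta(hours=arch.overreport_hours)
        self.time_logs.append(
            TimeLogEntry(self.interviewer_id, Activity.CALLING, shift_start, log_end)
        )

        t = shift_start
        dial_no = 0
        second = dt.timedelta(seconds=1)
        day_str = day.isoformat()
        cutoff = shift_end - dt.timedelta(minutes=2)
        while t < cutoff:
            dial_no += 1
            case_id = f"C-{self.interviewer_id}-{day_str}-{dial_no:03d}"
            call_id = f"call-{case_id}"
            version = Version.LONG if rng.random() < sim.version_mix else Version.SHORT
            target_s = sim.mean_interview_minutes[version.value] * 60.0
            target_s *= arch.question_time_scale

            disposition = Disposition(
                self._disp_names[bisect_right(self._disp_cum, rng.random())]
            )
            remaining = (shift_end - t).total_seconds()
            if (
                disposition in (Disposition.COMPLETE, Disposition.PARTIAL)
                and remaining < target_s * 1.5
            ):
                # no room for an interview before end of shift: call back later
                disposition = Disposition.NONCONTACT

            call_start = t
            stem_answers: dict[str, StemAnswer] = {}
            any_disorder: Optional[bool] = None
            if disposition is Disposition.COMPLETE:
                intro_s = 20.0 + 40.0 * rng.random()
                end, stem_answers, any_disorder = self._run_interview(
                    case_id, call_start + intro_s * second, version, None
                )
                call_end = end + (5.0 + 15.0 * rng.random()) * second
            elif disposition is Disposition.PARTIAL:
                intro_s = 20.0 + 40.0 * rng.random()
                end, stem_answers, any_disorder = self._run_interview(
                    case_id,
                    call_start + intro_s * second,
                    version,
                    0.1 + 0.4 * rng.random(),
                )
                call_end = end + (5.0 + 15.0 * rng.random()) * second
            elif disposition is Disposition.REFUSAL:
                call_end = call_start + (30.0 + 150.0 * rng.random()) * second
            elif disposition is Disposition.NONCONTACT:
                call_end = call_start + (15.0 + 30.0 * rng.random()) * second
            else:
                call_end = call_start + (20.0 + 100.0 * rng.random()) * second

            monitored: list[tuple[dt.datetime, dt.datetime]] = []
            call_len = (call_end - call_start).total_seconds()
            if disposition is Disposition.COMPLETE and rng.random() < sim.monitoring_rate:
                n_sessions = 1 + int(rng.random() < 0.3)
                for _ in range(n_sessions):
                    m_len = min(300.0 + 1500.0 * rng.random(), call_len)
                    m_off = (call_len - m_len) * rng.random()
                    monitored.append(
                        (
                            call_start + m_off * second,
                            call_start + (m_off + m_len) * second,
                        )
                    )

            self.call_records.append(
                CallRecord(call_id, self.interviewer_id, case_id, call_start, call_end, monitored)
            )
            self.case_records.append(
                CaseRecord(
                    case_id=case_id,
                    interviewer_id=self.interviewer_id,
                    version=version,
                    call_start=call_start,
                    call_end=call_end,
                    disposition=disposition,
                    respondent_gender=Gender.FEMALE if rng.random() < 0.5 else Gender.MALE,
                    stem_answers=stem_answers,
                    any_disorder=any_disorder,
                    attempt_number=int(rng.integers(1, 4)),
                )
            )
            t = call_end + (15.0 + 45.0 * rng.random()) * second


def generate_bundle(sim: SimConfig) -> ParadataBundle:
    """Generate a complete, internally consistent bundle; deterministic per seed."""
    catalog = make_catalog(sim)

    shift_seconds = min((b - a) * 3600 for a, b in sim.shifts)
    long_s = sim.mean_interview_minutes["LONG"] * 60.0
    if long_s * 1.5 > shift_seconds:
        raise InfeasibleConfigError(
            f"LONG interviews ({long_s / 60:.0f} min) do not fit a "
            f"{shift_seconds / 3600:.0f}h shift with headroom"
        )

    bundle = ParadataBundle(
        catalog=catalog,
        study_start_date=sim.start_date,
        provenance={"generator": "catiqc.synthetic_paradata", "seed": sim.seed},
    )
    for idx in range(1, sim.n_interviewers + 1):
        worker = _InterviewerSim(sim, idx, catalog)
        for d in range(sim.n_days):
            worker.run_day(sim.start_date + dt.timedelta(days=d))
        bundle.audit_events.extend(worker.audit_events)
        bundle.call_records.extend(worker.call_records)
        bundle.time_logs.extend(worker.time_logs)
        bundle.case_records.extend(worker.case_records)
    return bundle


def inject_archetype(
    sim: SimConfig, interviewer_id: str, archetype: str
) -> ParadataBundle:
    """Regenerate the bundle with one interviewer's archetype replaced.

    Because every interviewer draws from an isolated stream, all other
    interviewers' rows are identical to the original bundle's.
    """
    if interviewer_id not in sim.interviewer_ids():
        raise KeyError(f"unknown interviewer {interviewer_id!r}")
    if archetype not in ARCHETYPES:
        raise KeyError(f"unknown archetype {archetype!r}")
    assignment = dict(sim.archetype_assignment)
    assignment[interviewer_id] = archetype
    return generate_bundle(sim.model_copy(update={"archetype_assignment": assignment}))


def truth_table(sim: SimConfig) -> dict[str, str]:
    """Ground-truth archetype label per interviewer (for detection studies)."""
    return {
        ivw: sim.archetype_assignment.get(ivw, "COMPLIANT") for ivw in sim.interviewer_ids()
    }
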