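"""Shared fixtures: tiny hand-built bundles and a reusable simulator run."""
from __future__ import annotations

import datetime as dt

import pytest

from catiqc import pipeline, synthetic_paradata as sp
from catiqc.types import (
    AuditEvent,
    EventKind,
    QuestionCatalogEntry,
    UTC,
)

T0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)


def ts(seconds: float) -> dt.datetime:
    """Instant ``seconds`` after the canonical origin."""
    return T0 + dt.timedelta(seconds=seconds)


_EVENT_SEQ = {"n": 0}


def make_event(
    case_id: str,
    question_id: str,
    kind: EventKind,
    at: dt.datetime,
    interviewer_id: str = "I01",
    value: str | None = None,
) -> AuditEvent:
    _EVENT_SEQ["n"] += 1
    return AuditEvent(
        event_id=f"e{_EVENT_SEQ['n']:06d}",
        case_id=case_id,
        interviewer_id=interviewer_id,
        session_id=f"{case_id}-s1",
        question_id=question_id,
        kind=kind,
        timestamp=at,
        value=value,
    )


def enter(case_id, question_id, at, **kw):
    return make_event(case_id, question_id, EventKind.ENTER, at, **kw)


def exit_(case_id, question_id, at, **kw):
    return make_event(case_id, question_id, EventKind.EXIT, at, **kw)


@pytest.fixture
def catalog():
    return [
        QuestionCatalogEntry("q_stem1", "depression", True, 12.0, False),
        QuestionCatalogEntry("q_stem2", "worry_anxiety", True, 12.0, False),
        QuestionCatalogEntry("q1", "health", False, 8.0, False),
        QuestionCatalogEntry("q2", "health", False, 8.0, False),
        QuestionCatalogEntry("q3", "treatment", False, 60.0, False),
        QuestionCatalogEntry("q_intro", "intro", False, 2.0, True),
    ]


@pytest.fixture(scope="session")
def mixed_sim():
    """Small mixed-archetype scenario used across modules."""
    return sp.SimConfig(
        seed=11,
        n_interviewers=6,
        n_days=5,
        archetype_assignment={"I01": "SPEEDER", "I02": "FABRICATOR", "I03": "REVISITER"},
    )


@pytest.fixture(scope="session")
def mixed_bundle(mixed_sim):
    return sp.generate_bundle(mixed_sim)


@pytest.fixture(scope="session")
def mixed_result(mixed_bundle):
    return pipeline.run_pipeline(mixed_bundle)
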