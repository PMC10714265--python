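"""On-disk dialect for paradata bundles: parse, validate, serialize.

A bundle directory holds five CSV files plus ``bundle_meta.json``::

    audit_events.csv   call_records.csv   time_logs.csv
    case_records.csv   catalog.csv        bundle_meta.json

All files are UTF-8, comma-separated with quoted fields and a mandatory
header row. Timestamps are ISO-8601 with explicit offset and are
normalized to UTC in memory. Rows are written in a canonical sort order
so serialization is byte-stable.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

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
    parse_instant,
)

BUNDLE_FILES = (
    "audit_events.csv",
    "call_records.csv",
    "time_logs.csv",
    "case_records.csv",
    "catalog.csv",
)
META_FILE = "bundle_meta.json"

_STEM_CODE = {"POS": StemAnswer.POSITIVE, "NEG": StemAnswer.NEGATIVE, "MISS": StemAnswer.MISSING}
_STEM_CODE_INV = {v: k for k, v in _STEM_CODE.items()}


class BundleError(Exception):
    """Fatal bundle I/O or validation error."""


@dataclass
class StreamReport:
    rows_loaded: int = 0
    rows_dropped: int = 0
    issues: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    """Per-stream accounting of loaded vs dropped rows (lenient mode)."""

    streams: dict[str, StreamReport] = field(default_factory=dict)

    def stream(self, name: str) -> StreamReport:
        return self.streams.setdefault(name, StreamReport())

    @property
    def total_dropped(self) -> int:
        return sum(s.rows_dropped for s in self.streams.values())

    def to_dict(self) -> dict:
        return {
            name: {
                "rows_loaded": s.rows_loaded,
                "rows_dropped": s.rows_dropped,
                "issues": list(s.issues),
            }
            for name, s in sorted(self.streams.items())
        }


@dataclass
class CatalogIssue:
    kind: str  # duplicate | negative_baseline | stem_excluded | should_exclude
    question_id: str
    detail: str = ""


def _fmt_instant(ts: dt.datetime) -> str:
    return ts.isoformat()


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(text: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _fmt_intervals(intervals: list[tuple[dt.datetime, dt.datetime]]) -> str:
    return ";".join(f"{_fmt_instant(a)}|{_fmt_instant(b)}" for a, b in intervals)


def _parse_intervals(text: str) -> list[tuple[dt.datetime, dt.datetime]]:
    if not text:
        return []
    out = []
    for piece in text.split(";"):
        a, b = piece.split("|")
        out.append((parse_instant(a), parse_instant(b)))
    return out


def _fmt_stems(stems: dict[str, StemAnswer]) -> str:
    return ";".join(f"{q}={_STEM_CODE_INV[a]}" for q, a in sorted(stems.items()))


def _parse_stems(text: str) -> dict[str, StemAnswer]:
    if not text:
        return {}
    out = {}
    for piece in text.split(";"):
        q, code = piece.split("=")
        out[q] = _STEM_CODE[code]
    return out


# ---------------------------------------------------------------------------
# per-stream row codecs


def _audit_to_row(e: AuditEvent) -> list[str]:
    return [
        e.event_id,
        e.case_id,
        e.interviewer_id,
        e.session_id,
        e.question_id,
        e.kind.value,
        _fmt_instant(e.timestamp),
        e.value if e.value is not None else "",
    ]


def _audit_from_row(row: dict[str, str]) -> AuditEvent:
    ev = AuditEvent(
        event_id=row["event_id"],
        case_id=row["case_id"],
        interviewer_id=row["interviewer_id"],
        session_id=row["session_id"],
        question_id=row["question_id"],
        kind=EventKind(row["kind"]),
        timestamp=parse_instant(row["timestamp"]),
        value=row["value"] or None,
    )
    ev.validate()
    return ev


def _call_to_row(c: CallRecord) -> list[str]:
    return [
        c.call_id,
        c.interviewer_id,
        c.case_id,
        _fmt_instant(c.start),
        _fmt_instant(c.end),
        _fmt_intervals(c.monitored_intervals),
    ]


def _call_from_row(row: dict[str, str]) -> CallRecord:
    rec = CallRecord(
        call_id=row["call_id"],
        interviewer_id=row["interviewer_id"],
        case_id=row["case_id"],
        start=parse_instant(row["start"]),
        end=parse_instant(row["end"]),
        monitored_intervals=_parse_intervals(row["monitored_intervals"]),
    )
    rec.validate()
    return rec


def _timelog_to_row(t: TimeLogEntry) -> list[str]:
    return [t.interviewer_id, t.activity.value, _fmt_instant(t.start), _fmt_instant(t.end)]


def _timelog_from_row(row: dict[str, str]) -> TimeLogEntry:
    rec = TimeLogEntry(
        interviewer_id=row["interviewer_id"],
        activity=Activity(row["activity"]),
        start=parse_instant(row["start"]),
        end=parse_instant(row["end"]),
    )
    rec.validate()
    return rec


def _case_to_row(c: CaseRecord) -> list[str]:
    return [
        c.case_id,
        c.interviewer_id,
        c.version.value,
        _fmt_instant(c.call_start),
        _fmt_instant(c.call_end),
        c.disposition.value,
        c.respondent_gender.value if c.respondent_gender is not None else "",
        _fmt_stems(c.stem_answers),
        "" if c.any_disorder is None else _fmt_bool(c.any_disorder),
        str(c.attempt_number),
    ]


def _case_from_row(row: dict[str, str]) -> CaseRecord:
    rec = CaseRecord(
        case_id=row["case_id"],
        interviewer_id=row["interviewer_id"],
        version=Version(row["version"]),
        call_start=parse_instant(row["call_start"]),
        call_end=parse_instant(row["call_end"]),
        disposition=Disposition(row["disposition"]),
        respondent_gender=Gender(row["respondent_gender"]) if row["respondent_gender"] else None,
        stem_answers=_parse_stems(row["stem_answers"]),
        any_disorder=None if row["any_disorder"] == "" else _parse_bool(row["any_disorder"]),
        attempt_number=int(row["attempt_number"]),
    )
    rec.validate()
    return rec


def _catalog_to_row(q: QuestionCatalogEntry) -> list[str]:
    return [
        q.question_id,
        q.module,
        _fmt_bool(q.is_stem),
        repr(float(q.baseline_read_seconds)),
        _fmt_bool(q.exclude_from_short_flag),
    ]


def _catalog_from_row(row: dict[str, str]) -> QuestionCatalogEntry:
    rec = QuestionCatalogEntry(
        question_id=row["question_id"],
        module=row["module"],
        is_stem=_parse_bool(row["is_stem"]),
        baseline_read_seconds=float(row["baseline_read_seconds"]),
        exclude_from_short_flag=_parse_bool(row["exclude_from_short_flag"]),
    )
    rec.validate()
    return rec


_HEADERS = {
    "audit_events.csv": [
        "event_id", "case_id", "interviewer_id", "session_id", "question_id",
        "kind", "timestamp", "value",
    ],
    "call_records.csv": [
        "call_id", "interviewer_id", "case_id", "start", "end", "monitored_intervals",
    ],
    "time_logs.csv": ["interviewer_id", "activity", "start", "end"],
    "case_records.csv": [
        "case_id", "interviewer_id", "version", "call_start", "call_end",
        "disposition", "respondent_gender", "stem_answers", "any_disorder",
        "attempt_number",
    ],
    "catalog.csv": [
        "question_id", "module", "is_stem", "baseline_read_seconds",
        "exclude_from_short_flag",
    ],
}


def _read_stream(
    path: Path,
    filename: str,
    decode: Callable[[dict[str, str]], object],
    strict: bool,
    report: LoadReport,
) -> list:
    fpath = path / filename
    if not fpath.exists():
        raise BundleError(f"missing bundle file: {fpath}")
    out = []
    stream = report.stream(filename)
    with fpath.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _HEADERS[filename]:
            raise BundleError(
                f"{filename}: header {reader.fieldnames} does not match dialect "
                f"{_HEADERS[filename]}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                out.append(decode(row))
                stream.rows_loaded += 1
            except (ValueError, KeyError) as exc:
                if strict:
                    raise BundleError(f"{filename}:{i}: {exc}") from exc
                stream.rows_dropped += 1
                stream.issues.append(f"row {i}: {exc}")
    return out


def read_bundle(
    directory_path: str | Path, strict: bool = True
) -> tuple[ParadataBundle, LoadReport]:
    """Load and validate a bundle directory.

    In strict mode any invariant violation aborts with the offending row
    number; in lenient mode violating rows are dropped and counted in the
    returned :class:`LoadReport`.
    """
    path = Path(directory_path)
    report = LoadReport()

    catalog = _read_stream(path, "catalog.csv", _catalog_from_row, strict, report)
    seen: set[str] = set()
    for q in catalog:
        if q.question_id in seen:
            raise BundleError(f"catalog.csv: duplicate question_id {q.question_id!r}")
        seen.add(q.question_id)

    audit = _read_stream(path, "audit_events.csv", _audit_from_row, strict, report)
    calls = _read_stream(path, "call_records.csv", _call_from_row, strict, report)
    logs = _read_stream(path, "time_logs.csv", _timelog_from_row, strict, report)
    cases = _read_stream(path, "case_records.csv", _case_from_row, strict, report)

    # stem_answers keys must exist in the catalog and be stem questions
    stems = {q.question_id for q in catalog if q.is_stem}
    kept_cases = []
    stream = report.stream("case_records.csv")
    for c in cases:
        bad = [q for q in c.stem_answers if q not in stems]
        if bad:
            msg = f"case {c.case_id}: stem answers for non-stem/unknown questions {bad}"
            if strict:
                raise BundleError(f"case_records.csv: {msg}")
            stream.rows_loaded -= 1
            stream.rows_dropped += 1
            stream.issues.append(msg)
        else:
            kept_cases.append(c)

    # per-interviewer time-log overlap check
    by_ivw: dict[str, list[TimeLogEntry]] = {}
    for t in logs:
        by_ivw.setdefault(t.interviewer_id, []).append(t)
    kept_logs = []
    stream = report.stream("time_logs.csv")
    for ivw, entries in by_ivw.items():
        entries.sort(key=lambda t: (t.start, t.end))
        last_end: Optional[dt.datetime] = None
        for t in entries:
            if last_end is not None and t.start < last_end:
                msg = f"time log overlap for interviewer {ivw} at {t.start.isoformat()}"
                if strict:
                    raise BundleError(f"time_logs.csv: {msg}")
                stream.rows_loaded -= 1
                stream.rows_dropped += 1
                stream.issues.append(msg)
                continue
            last_end = t.end
            kept_logs.append(t)

    meta_path = path / META_FILE
    if not meta_path.exists():
        raise BundleError(f"missing bundle file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    bundle = ParadataBundle(
        audit_events=audit,
        call_records=calls,
        time_logs=kept_logs,
        case_records=kept_cases,
        catalog=catalog,
        study_start_date=dt.date.fromisoformat(meta["study_start_date"]),
        provenance=meta.get("provenance", {}),
    )
    return bundle, report


def write_bundle(bundle: ParadataBundle, directory_path: str | Path) -> Path:
    """Serialize a bundle in the canonical dialect; output is byte-stable."""
    path = Path(directory_path)
    path.mkdir(parents=True, exist_ok=True)

    def dump(filename: str, rows: list, encode: Callable, key: Callable) -> None:
        with (path / filename).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
            writer.writerow(_HEADERS[filename])
            for rec in sorted(rows, key=key):
                writer.writerow(encode(rec))

    dump(
        "audit_events.csv", bundle.audit_events, _audit_to_row,
        lambda e: (e.timestamp, e.case_id, e.event_id),
    )
    dump(
        "call_records.csv", bundle.call_records, _call_to_row,
        lambda c: (c.start, c.call_id),
    )
    dump(
        "time_logs.csv", bundle.time_logs, _timelog_to_row,
        lambda t: (t.interviewer_id, t.start),
    )
    dump(
        "case_records.csv", bundle.case_records, _case_to_row,
        lambda c: (c.call_start, c.case_id),
    )
    dump("catalog.csv", bundle.catalog, _catalog_to_row, lambda q: q.question_id)

    meta = {
        "study_start_date": bundle.study_start_date.isoformat(),
        "provenance": bundle.provenance,
    }
    (path / META_FILE).write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    return path


def validate_catalog(
    catalog: list[QuestionCatalogEntry], short_question_seconds: float = 3.0
) -> list[CatalogIssue]:
    """Report catalog problems without mutating the input.

    Issues: duplicate ids; negative baselines; stem questions marked
    excluded; entries whose baseline is below the short-question cutoff
    but that are not excluded from short-time flagging.
    """
    issues: list[CatalogIssue] = []
    seen: set[str] = set()
    for q in catalog:
        if q.question_id in seen:
            issues.append(CatalogIssue("duplicate", q.question_id))
        seen.add(q.question_id)
        if q.baseline_read_seconds < 0:
            issues.append(
                CatalogIssue("negative_baseline", q.question_id, f"{q.baseline_read_seconds}")
            )
        if q.is_stem and q.exclude_from_short_flag:
            issues.append(CatalogIssue("stem_excluded", q.question_id))
        if (
            q.baseline_read_seconds < short_question_seconds
            and not q.exclude_from_short_flag
            and not q.is_stem
        ):
            issues.append(
                CatalogIssue(
                    "should_exclude",
                    q.question_id,
                    f"baseline {q.baseline_read_seconds}s < cutoff {short_question_seconds}s",
                )
            )
    return issues
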