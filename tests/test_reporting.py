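import datetime as dt
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from catiqc import reporting
from catiqc.config import TaskRules
from catiqc.reporting import (
    EvaluationRecord,
    InvestigationTask,
    TaskStatus,
    build_task_queue,
    flag_summary,
    interviewer_profile,
    module_breakdown,
    monitoring_coverage,
    pct,
    visit_count_breakdown,
)
from catiqc.types import (
    CallRecord,
    Flag,
    FlagLevel,
    FlagType,
    UTC,
)

from conftest import ts

D = dt.date(2021, 2, 1)
WINDOW = (dt.date(2021, 1, 20), dt.date(2021, 2, 3))


def case_flag(ftype, case_id, ivw="I01", day=D, question_id=None, observed=1.0):
    return Flag(
        flag_type=ftype,
        level=FlagLevel.CASE,
        interviewer_id=ivw,
        case_id=case_id,
        question_id=question_id,
        observed_value=observed,
        threshold_value=0.0,
        triggered_at=day,
    )


def window_flag(ftype, ivw="I01", z=-2.5):
    return Flag(
        flag_type=ftype,
        level=FlagLevel.INTERVIEWER_WINDOW,
        interviewer_id=ivw,
        observed_value=z,
        threshold_value=1.5,
        window=WINDOW,
        triggered_at=WINDOW[1],
    )


# ---------------------------------------------------------------------------
# rounding


@settings(deadline=None, max_examples=200)
@given(n=st.integers(0, 100000), d=st.integers(1, 100000), digits=st.integers(0, 3))
def test_pct_is_half_up_of_exact_ratio(n, d, digits):
    got = pct(n, d, digits)
    exact = Fraction(100 * n, d)
    scale = Fraction(10) ** digits
    # half-up: floor(x*scale + 1/2) / scale
    expected = float((exact * scale + Fraction(1, 2)).__floor__() / scale)
    assert got == pytest.approx(expected, abs=10 ** (-digits - 6))


def test_pct_half_up_tie():
    assert pct(1, 8, 1) == 12.5
    assert pct(1, 800, 2) == 0.13  # 0.125 rounds up


# ---------------------------------------------------------------------------
# flag summary


class TestFlagSummary:
    def test_share_of_total_flags(self):
        flags = [
            case_flag(FlagType.MULTI_STEM_FIELD_VISITS, f"C{i}") for i in range(4584)
        ] + [case_flag(FlagType.SHORT_QUESTION_TIME, f"C{i}") for i in range(11035 - 4584)]
        rows = {r.flag_type: r for r in flag_summary(flags, 4496, 54850)}
        assert rows[FlagType.MULTI_STEM_FIELD_VISITS].pct_of_total_flags == 41.54

    def test_single_type_is_hundred_percent(self):
        flags = [case_flag(FlagType.SHORT_INTERVIEW, f"C{i}") for i in range(7)]
        rows = flag_summary(flags, 4496, 54850)
        assert len(rows) == 1
        assert rows[0].pct_of_total_flags == 100.0

    def test_touched_case_denominator(self):
        # 3224 flags over 1400 distinct touched cases
        flags = [
            case_flag(FlagType.SHORT_QUESTION_TIME, f"C{i % 1400}") for i in range(3224)
        ]
        rows = flag_summary(flags, 4496, 54850)
        row = rows[0]
        assert row.n_cases_flagged == 1400
        assert row.denominator_kind == reporting.DenominatorKind.TOUCHED_CASES
        assert row.pct_of_denominator == 2.55

    def test_completed_case_denominator(self):
        flags = [case_flag(FlagType.SHORT_INTERVIEW, f"C{i}") for i in range(268)]
        row = flag_summary(flags, 4496, 54850)[0]
        assert row.denominator_kind == reporting.DenominatorKind.COMPLETED_CASES
        assert row.pct_of_denominator == 5.96

    def test_conservation(self, mixed_result):
        flags = mixed_result.flags
        rows = flag_summary(flags, mixed_result.n_completed, mixed_result.n_touched)
        assert sum(r.n_flags for r in rows) == len(flags)
        assert sum(r.pct_of_total_flags for r in rows) == pytest.approx(100.0, abs=0.1)

    def test_zero_denominator_fatal(self):
        with pytest.raises(ValueError):
            flag_summary([case_flag(FlagType.SHORT_INTERVIEW, "C1")], 0, 100)


def test_module_breakdown():
    flags = [
        case_flag(FlagType.MULTI_STEM_FIELD_VISITS, f"C{i}", question_id="dep_q")
        for i in range(1243)
    ] + [
        case_flag(FlagType.MULTI_STEM_FIELD_VISITS, f"D{i}", question_id="other_q")
        for i in range(4584 - 1243)
    ]
    shares = module_breakdown(flags, {"dep_q": "depression", "other_q": "stressful"})
    assert shares["depression"] == (1243, 27.12)


def test_visit_count_breakdown():
    flags = [
        case_flag(FlagType.MULTI_STEM_FIELD_VISITS, f"C{i}", observed=2.0)
        for i in range(3300)
    ] + [
        case_flag(FlagType.MULTI_STEM_FIELD_VISITS, f"D{i}", observed=3.0)
        for i in range(4584 - 3300)
    ]
    shares = visit_count_breakdown(flags)
    assert shares[2][0] == 3300
    assert round(shares[2][1]) == 72


# ---------------------------------------------------------------------------
# monitoring coverage


def make_call(case_id, minutes_monitored, pieces=1, start_minute=0):
    t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC) + dt.timedelta(minutes=start_minute)
    end = t0 + dt.timedelta(minutes=max(minutes_monitored, 30))
    monitored = []
    offset = 0.0
    for _ in range(pieces):
        span = minutes_monitored / pieces
        monitored.append(
            (t0 + dt.timedelta(minutes=offset), t0 + dt.timedelta(minutes=offset + span))
        )
        offset += span
    return CallRecord(f"call-{case_id}", "I01", case_id, t0, end, monitored)


class TestMonitoringCoverage:
    def test_no_monitoring(self):
        calls = [make_call(f"C{i}", 0) for i in range(10)]
        report = monitoring_coverage(calls, {f"C{i}" for i in range(10)})
        assert report.monitored_hours == 0.0
        assert report.n_monitored_min == 0
        assert report.pct_any_monitoring == 0.0

    def test_printed_ratio_reproduction(self):
        completed = {f"C{i}" for i in range(4496)}
        calls = [make_call(f"C{i}", 20) for i in range(543)]
        calls += [make_call(f"C{i}", 5) for i in range(543, 944)]
        calls += [make_call(f"C{i}", 0) for i in range(944, 4496)]
        report = monitoring_coverage(calls, completed, min_minutes=15)
        assert report.n_monitored_min == 543
        assert report.pct_monitored_min == 12.08
        assert report.n_any_monitoring == 944
        assert reporting.round_half_up(report.pct_any_monitoring, 0) == 21

    def test_overlap_merged_before_threshold(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        call = CallRecord(
            "c", "I01", "C1", t0, t0 + dt.timedelta(minutes=40),
            monitored_intervals=[
                (t0, t0 + dt.timedelta(minutes=10)),
                (t0 + dt.timedelta(minutes=5), t0 + dt.timedelta(minutes=14)),
            ],
        )
        report = monitoring_coverage([call], {"C1"}, min_minutes=15)
        assert report.n_monitored_min == 0  # merged 14 min, not 15
        assert report.n_any_monitoring == 1

    def test_union_matches_minute_grid(self):
        import random

        rng = random.Random(1)
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        monitored = []
        grid = set()
        for _ in range(8):
            a = rng.randrange(0, 100)
            b = rng.randrange(a, 120)
            monitored.append((t0 + dt.timedelta(minutes=a), t0 + dt.timedelta(minutes=b)))
            grid.update(range(a, b))
        call = CallRecord("c", "I01", "C1", t0, t0 + dt.timedelta(minutes=120), monitored)
        report = monitoring_coverage([call], {"C1"})
        assert report.monitored_hours * 60 == pytest.approx(len(grid))


# ---------------------------------------------------------------------------
# task queue


class TestTaskQueue:
    period = (dt.date(2021, 1, 20), dt.date(2021, 2, 3))

    def test_empty(self):
        assert build_task_queue([], self.period) == []

    def test_window_flag_gives_high_priority(self):
        flags = [window_flag(FlagType.PREVALENCE_RATE)]
        tasks = build_task_queue(flags, self.period)
        assert len(tasks) == 1
        assert tasks[0].priority == "HIGH"

    def test_one_task_per_interviewer(self):
        flags = [
            case_flag(FlagType.SHORT_QUESTION_TIME, f"C{i}", ivw=f"I{i:02d}")
            for i in range(5)
        ]
        tasks = build_task_queue(flags, self.period)
        assert len(tasks) == 5
        assert {t.interviewer_id for t in tasks} == {f"I{i:02d}" for i in range(5)}

    def test_priority_thresholds(self):
        flags = [case_flag(FlagType.SHORT_QUESTION_TIME, f"C{i}") for i in range(10)]
        assert build_task_queue(flags, self.period)[0].priority == "HIGH"
        assert build_task_queue(flags[:3], self.period)[0].priority == "MEDIUM"
        assert build_task_queue(flags[:2], self.period)[0].priority == "LOW"
        rules = TaskRules(high_count=2, med_count=1)
        assert build_task_queue(flags[:2], self.period, rules)[0].priority == "HIGH"

    def test_queue_totality(self, mixed_result):
        flags = mixed_result.flags
        tasks = build_task_queue(flags, self.period)
        seen: list[int] = []
        for t in tasks:
            seen.extend(t.flag_ids)
        assert sorted(seen) == list(range(len(flags)))

    def test_flags_sorted_newest_first(self):
        flags = [
            case_flag(FlagType.SHORT_QUESTION_TIME, "C1", day=dt.date(2021, 1, 21)),
            case_flag(FlagType.SHORT_QUESTION_TIME, "C2", day=dt.date(2021, 1, 25)),
        ]
        task = build_task_queue(flags, self.period)[0]
        assert task.flag_ids == [1, 0]

    def test_status_machine(self):
        task = InvestigationTask("t", "I01", self.period, [], "LOW")
        task.advance(TaskStatus.ASSIGNED_MONITORING, "sent to monitors", at=ts(0))
        task.advance(TaskStatus.RESOLVED, "ok", at=ts(60))
        assert [n[1] for n in task.notes] == ["sent to monitors", "ok"]
        with pytest.raises(ValueError):
            task.advance(TaskStatus.OPEN)

    def test_open_to_resolved_allowed(self):
        task = InvestigationTask("t", "I01", self.period, [], "LOW")
        task.advance(TaskStatus.RESOLVED)
        assert task.status == TaskStatus.RESOLVED


# ---------------------------------------------------------------------------
# profiles & evaluations


class TestProfiles:
    def test_no_activity_profile_of_zeros(self):
        profile = interviewer_profile("I42", [], [], [], known_interviewers={"I42"})
        assert profile["n_flags"] == 0
        assert set(profile["flags_by_category"].values()) == {0}

    def test_unknown_interviewer_fatal(self):
        with pytest.raises(KeyError):
            interviewer_profile("I42", [], [], [], known_interviewers={"I01"})

    def test_totals_match_flag_export(self, mixed_result):
        profile = interviewer_profile(
            "I01", mixed_result.flags, mixed_result.metrics, mixed_result.window_stats
        )
        direct = [f for f in mixed_result.flags if f.interviewer_id == "I01"]
        assert profile["n_flags"] == len(direct)
        assert sum(profile["flags_by_type"].values()) == len(direct)

    def test_speeder_profile_duration_dominant(self, mixed_result):
        profile = interviewer_profile(
            "I01", mixed_result.flags, mixed_result.metrics, mixed_result.window_stats
        )
        cats = profile["flags_by_category"]
        assert cats["duration"] > cats["cidi"]
        assert cats["duration"] > cats["operational"]

    def test_category_filter(self, mixed_result):
        profile = interviewer_profile(
            "I01",
            mixed_result.flags,
            mixed_result.metrics,
            mixed_result.window_stats,
            category="duration",
        )
        assert profile["flags_by_category"]["cidi"] == 0


class TestEvaluationRecord:
    def test_valid(self):
        rec = EvaluationRecord(
            "I01", dt.date(2021, 2, 1), {s: 4 for s in reporting.SKILLS}
        )
        rec.validate()

    def test_score_out_of_range(self):
        scores = {s: 4 for s in reporting.SKILLS}
        scores["probing"] = 6
        with pytest.raises(ValueError):
            EvaluationRecord("I01", dt.date(2021, 2, 1), scores).validate()

    def test_wrong_skill_set(self):
        with pytest.raises(ValueError):
            EvaluationRecord("I01", dt.date(2021, 2, 1), {"typing": 3}).validate()
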