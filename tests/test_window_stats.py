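import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catiqc import synthetic_paradata as sp, window_stats as ws
from catiqc import intervals, pipeline
from catiqc.config import ThresholdConfig
from catiqc.types import (
    Activity,
    CallRecord,
    CaseRecord,
    Disposition,
    FlagType,
    Metric,
    ParadataBundle,
    Statistic,
    TimeLogEntry,
    UTC,
    Version,
    WindowStat,
)

CFG = ThresholdConfig()
START = dt.date(2021, 1, 20)


def stat(ivw, value, n_cases=20, statistic=Statistic.PREVALENCE, w=None):
    w = w or (START, START + dt.timedelta(days=14))
    return WindowStat(ivw, w, statistic, n_cases, value)


class TestPartitionWindows:
    def test_single_case_single_window(self):
        wins = ws.partition_windows(START, [dt.date(2021, 1, 25)])
        assert wins == [(START, dt.date(2021, 2, 3))]

    def test_boundary_date_opens_later_window(self):
        w = ws.window_of(dt.date(2021, 2, 3), START)
        assert w == (dt.date(2021, 2, 3), dt.date(2021, 2, 17))

    def test_sixty_days_disjoint_cover(self):
        dates = [START + dt.timedelta(days=i) for i in range(60)]
        wins = ws.partition_windows(START, dates)
        assert len(wins) == 5
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            assert b1 == a2  # abutting, disjoint half-open
        for d in dates:
            assert any(a <= d < b for a, b in wins)
        assert all(ws.window_of(d, START) in wins for d in dates)

    def test_empty_dates(self):
        assert ws.partition_windows(START, []) == []

    def test_date_before_start_rejected(self):
        with pytest.raises(ValueError):
            ws.partition_windows(START, [dt.date(2021, 1, 1)])


class TestWindowZscores:
    def test_hand_computed_example(self):
        stats = [stat("A", 60.0), stat("B", 90.0), stat("C", 90.0)]
        out = ws.window_zscores(stats, CFG)
        z = {s.interviewer_id: s.z for s in out}
        assert z["A"] == pytest.approx(-1.1547, abs=1e-4)
        assert z["B"] == pytest.approx(0.5774, abs=1e-4)

    def test_all_equal_values_z_null(self):
        out = ws.window_zscores([stat("A", 0.4), stat("B", 0.4), stat("C", 0.4)], CFG)
        assert all(s.z is None for s in out)

    def test_ineligible_interviewer_gets_null(self):
        stats = [stat("A", 60.0), stat("B", 90.0), stat("tiny", 10.0, n_cases=2)]
        out = ws.window_zscores(stats, CFG)
        z = {s.interviewer_id: s.z for s in out}
        assert z["tiny"] is None
        assert z["A"] is not None

    def test_fewer_than_two_eligible_all_null(self):
        stats = [stat("A", 60.0), stat("tiny", 10.0, n_cases=1)]
        out = ws.window_zscores(stats, CFG)
        assert all(s.z is None for s in out)

    def test_eligible_zscores_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        stats = [stat(f"I{i}", float(v)) for i, v in enumerate(rng.normal(50, 8, 15))]
        out = ws.window_zscores(stats, CFG)
        zs = np.array([s.z for s in out])
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=1) - 1.0) < 1e-9


class TestEmitWindowFlags:
    def test_prevalence_boundary_exact_cutoff_no_flag(self):
        s = stat("A", 0.2)
        s.z = -1.5
        assert ws.emit_window_flags([s], CFG) == []

    def test_prevalence_just_past_cutoff_flags(self):
        s = stat("A", 0.2)
        s.z = -1.51
        flags = ws.emit_window_flags([s], CFG)
        assert [f.flag_type for f in flags] == [FlagType.PREVALENCE_RATE]
        assert flags[0].observed_value == -1.51

    def test_positive_prevalence_flags_with_sign(self):
        s = stat("A", 0.8)
        s.z = 2.47
        flags = ws.emit_window_flags([s], CFG)
        assert flags[0].observed_value == 2.47

    def test_short_avg_flag_at_exact_minus_two(self):
        s = stat("A", 60.0, statistic=Statistic.MEAN_INTERVIEW_MINUTES)
        s.z = -2.0
        flags = ws.emit_window_flags([s], CFG)
        assert [f.flag_type for f in flags] == [FlagType.SHORT_AVG_INTERVIEW]

    def test_short_avg_above_cutoff_no_flag(self):
        s = stat("A", 60.0, statistic=Statistic.MEAN_INTERVIEW_MINUTES)
        s.z = -1.99
        assert ws.emit_window_flags([s], CFG) == []


def make_complete(case_id, ivw, day_offset, disorder):
    start = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC) + dt.timedelta(days=day_offset)
    return CaseRecord(
        case_id=case_id,
        interviewer_id=ivw,
        version=Version.LONG,
        call_start=start,
        call_end=start + dt.timedelta(hours=1),
        disposition=Disposition.COMPLETE,
        any_disorder=disorder,
    )


class TestPrevalenceStat:
    def test_zero_disorders(self):
        cases = [make_complete(f"C{i}", "A", 0, False) for i in range(8)]
        stats = ws.prevalence_stat(cases, START)
        assert len(stats) == 1
        assert stats[0].value == 0.0
        assert stats[0].n_cases == 8

    def test_half_disorders(self):
        cases = [make_complete(f"C{i}", "A", 0, i < 5) for i in range(10)]
        stats = ws.prevalence_stat(cases, START)
        assert stats[0].value == 0.5

    def test_incomplete_cases_excluded(self):
        cases = [make_complete(f"C{i}", "A", 0, True) for i in range(3)]
        refusal = make_complete("R", "A", 0, None)
        refusal.disposition = Disposition.REFUSAL
        refusal.any_disorder = None
        stats = ws.prevalence_stat(cases + [refusal], START)
        assert stats[0].n_cases == 3


class TestComputeMetrics:
    period = (dt.date(2021, 1, 20), dt.date(2021, 1, 21))

    def _base_bundle(self, calls=(), logs=(), cases=()):
        return ParadataBundle(
            call_records=list(calls), time_logs=list(logs), case_records=list(cases)
        )

    def test_dials_per_hour(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        calls = [
            CallRecord(f"c{i}", "A", f"C{i}", t0 + dt.timedelta(minutes=10 * i),
                       t0 + dt.timedelta(minutes=10 * i + 5))
            for i in range(30)
        ]
        logs = [TimeLogEntry("A", Activity.CALLING, t0, t0 + dt.timedelta(hours=5))]
        metrics = ws.compute_metrics(self._base_bundle(calls, logs), [], {}, self.period)
        by = {m.metric: m.value for m in metrics if m.case_id is None}
        assert by[Metric.DIALS_PER_HOUR] == pytest.approx(6.0)
        assert by[Metric.CISCO_CALLING_TIME] == pytest.approx(2.5)

    def test_reported_time_discrepancy(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        calls = [CallRecord("c1", "A", "C1", t0, t0 + dt.timedelta(hours=6.5))]
        logs = [TimeLogEntry("A", Activity.CALLING, t0, t0 + dt.timedelta(hours=8))]
        metrics = ws.compute_metrics(self._base_bundle(calls, logs), [], {}, self.period)
        by = {m.metric: m.value for m in metrics}
        assert by[Metric.REPORTED_TIME_DISCREPANCY] == pytest.approx(1.5)

    def test_overlapping_monitoring_merged(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        call = CallRecord(
            "c1", "A", "C1", t0, t0 + dt.timedelta(minutes=30),
            monitored_intervals=[
                (t0, t0 + dt.timedelta(minutes=10)),
                (t0 + dt.timedelta(minutes=5), t0 + dt.timedelta(minutes=20)),
            ],
        )
        metrics = ws.compute_metrics(self._base_bundle([call]), [], {}, self.period)
        per_case = [m for m in metrics if m.metric is Metric.MONITORING_TIME_PER_CASE]
        assert len(per_case) == 1
        assert per_case[0].value == pytest.approx(20.0)
        by = {m.metric: m.value for m in metrics if m.case_id is None}
        assert by[Metric.MONITORING_TIME_PER_INTERVIEWER] == pytest.approx(20.0)
        assert by[Metric.MONITORED] is True

    def test_empty_period_yields_zero_metrics(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        logs = [TimeLogEntry("A", Activity.SHIFT_PREP, t0, t0 + dt.timedelta(hours=1))]
        metrics = ws.compute_metrics(self._base_bundle(logs=logs), [], {}, self.period)
        by = {m.metric: m.value for m in metrics}
        assert by[Metric.MONITORED] is False
        assert by[Metric.DIALS_PER_HOUR] == 0.0
        assert by[Metric.ADJ_COMPLETES_PER_HOUR] == 0.0

    def test_after_call_work_time(self):
        t0 = dt.datetime(2021, 1, 20, 9, 0, tzinfo=UTC)
        calls = [
            CallRecord("c1", "A", "C1", t0, t0 + dt.timedelta(minutes=5)),
            CallRecord("c2", "A", "C2", t0 + dt.timedelta(minutes=6),
                       t0 + dt.timedelta(minutes=10)),
            CallRecord("c3", "A", "C3", t0 + dt.timedelta(minutes=12),
                       t0 + dt.timedelta(minutes=15)),
        ]
        logs = [TimeLogEntry("A", Activity.CALLING, t0, t0 + dt.timedelta(hours=6))]
        metrics = ws.compute_metrics(self._base_bundle(calls, logs), [], {}, self.period)
        by = {m.metric: m.value for m in metrics}
        assert by[Metric.AVG_AFTER_CALL_WORK_TIME] == pytest.approx(90.0)  # (60+120)/2

    def test_metric_names_cover_box_list(self, mixed_bundle, mixed_result):
        assert len(Metric) == 14
        period = (mixed_bundle.study_start_date, dt.date(2021, 3, 1))
        metrics = ws.compute_metrics(
            mixed_bundle, mixed_result.visits, mixed_result.timelines, period
        )
        assert {m.metric for m in metrics} == set(Metric)


# ---------------------------------------------------------------------------
# interval properties


@settings(deadline=None, max_examples=100)
@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(0, 5000)).map(
            lambda p: (min(p), max(p))
        ),
        max_size=12,
    )
)
def test_interval_union_matches_grid_oracle(pairs):
    got = sum(b - a for a, b in intervals.merge(pairs))
    covered = set()
    for a, b in pairs:
        covered.update(range(a, b))
    assert got == len(covered)


@settings(deadline=None, max_examples=60)
@given(
    st.lists(
        st.tuples(st.integers(0, 2000), st.integers(0, 2000)).map(
            lambda p: (min(p), max(p))
        ),
        max_size=10,
    ),
    st.tuples(st.integers(0, 2000), st.integers(0, 2000)).map(lambda p: (min(p), max(p))),
)
def test_adding_interval_never_decreases_union(pairs, extra):
    before = sum(b - a for a, b in intervals.merge(pairs))
    after = sum(b - a for a, b in intervals.merge(pairs + [extra]))
    assert after >= before


# ---------------------------------------------------------------------------
# parameter recovery (scaled-down): one interviewer whose true interview
# length is shifted far below the population mean must be caught, and
# compliant interviewers must rarely be flagged.


def test_parameter_recovery_short_average_interview():
    sp.ARCHETYPES["_SHIFTED"] = sp.ArchetypeConfig(name="_SHIFTED", question_time_scale=0.90)
    try:
        n_seeds = 15
        caught = 0
        compliant_flagged = 0
        compliant_pairs = 0
        for seed in range(n_seeds):
            sim = sp.SimConfig(
                seed=seed,
                n_interviewers=10,
                n_days=14,
                version_mix=1.0,  # one version, so mean length is comparable
                archetype_assignment={"I01": "_SHIFTED"},
            )
            bundle = sp.generate_bundle(sim)
            res = pipeline.run_pipeline(bundle, compute_metrics=False)
            mine = [
                f
                for f in res.flags
                if f.flag_type is FlagType.SHORT_AVG_INTERVIEW
            ]
            if any(f.interviewer_id == "I01" for f in mine):
                caught += 1
            others = {f.interviewer_id for f in mine if f.interviewer_id != "I01"}
            compliant_flagged += len(others)
            compliant_pairs += 9
        assert caught >= int(0.95 * n_seeds)
        assert compliant_flagged / compliant_pairs <= 0.10
    finally:
        del sp.ARCHETYPES["_SHIFTED"]
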