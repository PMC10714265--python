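# catiqc

Quality-control indicator engine for CATI (computer-assisted telephone
interviewing) survey paradata. From four raw paradata streams — software
audit trails, call detail records, case/response records, and interviewer
time-tracker logs — the engine reconstructs per-question field visits and
interview timelines, computes thirteen case- and window-level quality
flags plus thirteen verification metrics, standardizes two-week
interviewer statistics into z-score flags, accounts for live-monitoring
coverage, and builds a prioritized per-interviewer investigation task
queue. A seeded synthetic-paradata simulator with interviewer behavior
archetypes (compliant, speeder, fabricator, revisiter, slowpoke) makes the
whole pipeline exercisable without any real data.

## Layout

| module | role |
|---|---|
| `catiqc.ingest_io` | bundle dialect: parse, validate, serialize the five CSV streams |
| `catiqc.session_builder` | ENTER/EXIT pairing into field visits, visit counts, timelines |
| `catiqc.flag_engine` | case-level flags (question times, visits, interview profile, completes rate) |
| `catiqc.window_stats` | tumbling 14-day windows, cross-interviewer z-scores, verification metrics |
| `catiqc.synthetic_paradata` | seeded bundle generator with archetype injection and truth table |
| `catiqc.reporting` | flag summary, monitoring coverage, task queue, profiles, exports |
| `catiqc.pipeline` / `catiqc.cli` | orchestration and the `catiqc` command |

## CLI

```sh
# generate a synthetic bundle (plus truth.json with the archetype labels)
catiqc simulate --config sim.yaml --seed 7 --out bundle/

# validate a bundle directory (exit code 2 on validation failure)
catiqc validate --bundle bundle/ --strict

# run the engine and write reports
catiqc run --bundle bundle/ --config qc.yaml --out reports/
```

`reports/` contains `flags.csv`, `summary.csv`, `metrics.csv`,
`window_stats.csv`, `visits.csv`, `timelines.csv`, `coverage.json`,
`tasks.json` and `profiles/<interviewer>.json`. Threshold configuration is
a YAML file mirroring `catiqc.config.ThresholdConfig` field names; all
cutoffs (3 s short question, 7 min long pause, visit cutoffs 1/3,
30% short share, |z| > 1.5 prevalence, z ≤ −2 short average, 14-day
windows, ...) are configurable.

## Bundle format

A bundle directory holds UTF-8 CSV files with mandatory headers —
`audit_events.csv`, `call_records.csv`, `time_logs.csv`,
`case_records.csv`, `catalog.csv` — plus `bundle_meta.json` (study start
date, provenance). Timestamps are ISO-8601 with explicit offsets,
normalized to UTC internally; intervals are half-open `[start, end)`.
Serialization is canonical (sorted rows), so writing the same bundle twice
is byte-identical.
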