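# hemovigil

Audit-grade monitoring of blood-transfusion documentation from EMR data.

Australian hospitals must demonstrate compliance with the NSQHS Blood
Management standard (Standard 7): every transfusion needs documented
consent, a compatibility check, a completion record, and vital-sign
observations (temperature, pulse, blood pressure, respiratory rate) on a
fixed schedule.  The EMR, however, stores none of this as "a transfusion".
It stores a long-format stream of independent clinical events — one row
per Initiate, per Complete, per consent acknowledgement, per vital-sign
reading — linked only by encounter and timestamp, with retrospective
corrections appended as new row versions rather than edits.

`hemovigil` turns that stream into auditable compliance metrics:

1. **Event store** — keeps, per logical event key, the highest
   `UPDT_CNT` version; superseded and stale deliveries are logged and
   excluded from all computation.  Ingestion converges to the same state
   for any batch frequency or ordering.
2. **Reconstruction** — one episode per active Initiate; each Complete
   matches the latest unmatched Initiate at or before it within the
   encounter (ambiguity flagged for concurrent transfusions); consent,
   compatibility and observations are attached by time windows.
3. **Compliance scoring** — for an episode starting at *s* and ending at
   *e*, all four vital-sign categories must appear in each closed window:

   | interval   | window (minutes)                                         |
   |------------|----------------------------------------------------------|
   | baseline   | [*s* − 60, *s* + 5]                                      |
   | 15-minute  | [*s* + 15 ± 5]                                           |
   | hourly *k* | [*s* + 60*k* ± 20] ∪ [*t*₁₅ + 60*k* ± 20], required iff *e* > *s* + 60*k* |
   | post       | [*e*, *e* + 60], not assessable without a Complete        |

   where *t*₁₅ is the earliest observation inside the 15-minute window
   (the alternative anchor for hourly observations), and up to three
   hourly subintervals are scored.
4. **Warehouse** — an event-granularity `TRANSFUSION` table with
   precomputed flags and a `TRANSFUSION_DAILY_FACT` table aggregated per
   (date, facility, ward, medical service), persisted in SQLite; status
   and history views compare each measure against a configurable target
   (default 80 %).

Because hospital extracts cannot be shared, the package ships a synthetic
EMR generator (`hemovigil.synthetic_emr`) that emits raw long-format
extracts with known ground truth, including missing completions,
partially documented intervals, concurrent transfusions and versioned
corrections.

## Worked example

```sh
hemovigil simulate --out-dir extracts --n-encounters 60 --seed 7 --batching daily
hemovigil ingest --warehouse wh.sqlite extracts/*.csv
hemovigil report --warehouse wh.sqlite --view status --month 2021-12 --out-dir reports
```

The simulate step writes 65 daily extract files; ingest prints

```
ingested 2486 rows (0 rejected): 2392 inserted, 68 replaced, 0 stale;
warehouse now holds 95 episodes
```

(68 rows were corrections superseding earlier versions), and the status
report for December 2021 prints

```
      measure  numerator  denominator     rate  target   met  defined
      consent         43           44 0.977273     0.8  True     True
compatibility         40           44 0.909091     0.8  True     True
   completion         35           44 0.795455     0.8 False     True
     baseline         40           44 0.909091     0.8  True     True
        min15         29           44 0.659091     0.8 False     True
       hourly         25           44 0.568182     0.8 False     True
         post         26           35 0.742857     0.8 False     True
```

44 transfusions started in December; 43 had documented consent (97.7 %,
meeting the 80 % target), while only 29 documented all four vital signs
in the 15-minute window (65.9 %, missing the target).  The post measure
is scored only over the 35 episodes whose completion was documented.
The same library calls are available programmatically
(`Pipeline.ingest_records`, `warehouse.status_view`,
`warehouse.history_view`), and the history view supports year, month,
day and hour-of-day granularity with hospital/ward/medical-service
filters.

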