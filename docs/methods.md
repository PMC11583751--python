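# Methods

## The problem being modelled

A transfusion in a transactional EMR is not a record but a scatter of
clinical events: an Initiate, possibly a Complete, a consent
acknowledgement, a compatibility check, and vital-sign readings, each an
independent row identified by patient/encounter keys and a timestamp.
Three properties of this data drive the whole design:

* **No linkage.** Nothing ties a Complete to its Initiate, or an
  observation to a transfusion.  Episodes must be reconstructed by
  time-and-encounter rules, and the reconstruction is genuinely ambiguous
  when a patient receives concurrent transfusions.
* **Append-only corrections.** Fixing a mis-entered time produces a new
  row with the same logical event key, an incremented `UPDT_CNT` and a new
  physical row id; the wrong row stays in the database.  Any later extract
  can therefore invalidate rows already ingested.
* **Batch extraction at arbitrary frequency.** Extracts may arrive
  monthly, daily or hourly; an episode's rows routinely span batches.

## Event versioning

The store partitions every upserted row into *active* (highest version
per key), *superseded* (replaced by a higher version) and *stale*
(arrived with a version at or below the active one).  Two identifiers are
deliberately distinct: `ROW_ID` names a physical row and changes with
every correction, `EVENT_KEY` names the logical event and is stable, with
`UPDT_CNT` ordering its versions.  This makes "a correction gets a new
unique identifier" and "the new record replaces the old one under the
unique key" simultaneously true and testable.  Because versions are
totally ordered per key, the active set is invariant under batch
permutation, and re-ingestion is idempotent — the properties the
order-insensitivity and conservation tests assert.  Stale deliveries are
logged, never errors: out-of-order batches must converge.  Two rows with
the same `(event_key, updt_cnt)` but different payloads are a hard error;
no real source can produce them, so silence would hide corruption.

## Reconstruction rules

* One episode per active Initiate, always; Initiates are never inferred.
* A Complete matches, within its encounter, the latest not-yet-matched
  Initiate at or before its own time — the only causally sound reading of
  "closest previous".  Ties (simultaneous Initiates) break on the smaller
  event key for determinism.  When more than one candidate existed the
  episode carries an ambiguity flag, because concurrent-transfusion
  matching is inherently unreliable; a Complete with no candidate becomes
  an orphan, never an episode.
* Consent and compatibility attach from a lookback window
  (default 24 h before start, through start + 5 min).  The 24 h figure is
  a policy default exposed in `WindowPolicy`, not a claim about any
  specific hospital's consent-validity rule; the latest qualifying record
  wins.
* Observations attach over [start − 60 min, horizon], where the horizon
  is end + 60 min for closed episodes and start + 60·(max hourly) + 60
  for open ones (bounding attachment when no Complete exists).
  Observations are measured on the patient, so concurrent episodes share
  them rather than each demanding private rows.
* Incremental processing after an upsert rebuilds exactly the encounters
  the changeset touched.  Its contract — bit-identical to a one-shot
  rebuild of the active set — is the package's central test, since all
  matching and attachment is local to an encounter.

## Compliance scoring

All interval bounds are closed ("up to 5 minutes after" includes minute
5); all parameters are integer minutes in `WindowPolicy`:

| parameter | default | meaning |
|---|---|---|
| `baseline_before_min` / `baseline_after_min` | 60 / 5 | baseline window around start |
| `t15_nominal_min` ± `t15_grace_min` | 15 ± 5 | 15-minute window |
| `hourly_grace_min` | 20 | grace around each hourly point |
| `hourly_max_subintervals` | 3 | hourly subintervals scored |
| `post_window_min` | 60 | window after completion |
| `consent_lookback_min` | 1440 | consent/compatibility lookback |
| `open_episode_policy` | ASSUME_MAX | hourly requirement without a Complete |

The hourly subinterval *k* is the union of windows around start + 60*k*
and around *t*₁₅ + 60*k*, where *t*₁₅ is the earliest attributed
observation in the 15-minute window.  The dual anchor is applied to every
hourly subinterval, not chained from the previous hourly observation;
chaining is a plausible alternative reading and the union is the most
permissive choice consistent with "in relation to either the start or the
15-minute observation".  Hour *k* is required only while the transfusion
is still running (end > start + 60*k*).  Without a completion record the
post measure is `NOT_ASSESSABLE` and the hourly requirement follows the
open-episode policy: `ASSUME_MAX` (default — a missing completion never
excuses missing observations in an audit) requires every subinterval,
`CENSOR` (for sensitivity analysis) requires hour *k* only when the last
attributed event proves the episode was still running at the window's
close.  A category is satisfied by any of its source forms (e.g. systolic
or diastolic rows both satisfy blood pressure).

The evaluator is validated against a deliberately naive oracle
(`tests/oracle.py`): windows re-derived with explicit arithmetic and
nested containment loops, compared field-by-field on simulated cohorts
under both open-episode policies and on constructed boundary cases.

## Warehouse

`TRANSFUSION` holds one row per episode with dimensions, foreign keys to
attached records and precomputed flags; `TRANSFUSION_DAILY_FACT`
aggregates counts per (date, facility, ward, medical service).  The fact
table exists for query speed only: every fact-derived statistic must
equal its event-level recomputation, before and after correction batches
— enforced by the consistency tests and helpers
(`missing_consents_from_events`, `rates_from_events`).  The post measure's
denominator is the number of completion-documented episodes, so one
missing completion is penalized once (on the completion measure) rather
than twice; completion counts remain in every export so the
missing-completion population stays visible.  Hour-of-day history
recomputes from the event level, since daily facts cannot resolve hours.
Measure targets default to 0.80 and are overridable per measure.

## Synthetic EMR generator

The generator emulates the *structure* of EMR transfusion data, not its
clinical content: long-format rows only; multi-record episodes; missing
completion records (`p_completion_recorded`, default 0.85); per-interval
documentation gaps (`p_obs_interval`, default 0.8 — around the audit
target region, where pass/fail boundaries are actually exercised);
concurrent episodes sharing encounter-level observations
(`p_concurrent`, default 0.10); and retrospective corrections
(`p_correction`, default 0.05 — real correction frequency is unknown, so
this is a harness choice).  Defaults describe ~120 encounters over a
three-month span across 3 facilities × 2 wards × 4 services.
Observation values are plausible numbers (e.g. pulse ~ N(80, 12²)) but
carry no clinical signal; value plausibility, order details beyond
product type, and adverse events are explicitly not modelled, so passing
tests say nothing about those aspects of real data.

Two design points matter for correctness of the ground truth:

* **Exclusive placement zones.** Schedule windows can overlap (the post
  window [e, e+60] intersects the hour-*k* window whenever
  e ≤ s + 60k + 20, and a late *t*₁₅ lets adjacent hourly windows touch).
  An observation emitted for one interval could then accidentally satisfy
  another, decoupling the Bernoulli documentation draw from the resulting
  flag.  Each interval's rows are therefore placed uniformly over the
  minutes of its own window *not* covered by any other scored interval's
  window set; under the default schedule these zones are provably
  non-empty (a guard falls back to the full window).  Observations are
  emitted at minute resolution because every schedule parameter is in
  minutes.
* **Containment-recomputed truth.** After emission (and again after
  corrections, which can move an Initiate earlier or a Complete later),
  per-episode flags are recomputed from the highest-version rows by
  direct window containment.  Ground truth therefore stays exact even
  when a correction reshapes the schedule or a concurrent episode
  borrows observations.

Corrections perturb timestamps only for Initiate (earlier by 5–45 min)
and Complete (later by 5–45 min) rows and values otherwise; each
correction is batch-assigned at its correction time (event time plus a
0.5 h–2 d delay), which is how a correction lands in a later extract than
the row it supersedes.  Determinism is strict: a fixed config yields
byte-identical extract files.

## Numerical and procedural choices

* Timestamps are naive local time at minute precision; timezone handling
  is out of scope (single-network data).  Timestamps outside 1990–2100
  reject as bad data.
* Rows missing a critical column (event key, encounter, result name,
  timestamp, version) are rejected with a reason, never silently dropped;
  unknown result names classify as `OTHER` and are retained.
* All orderings are made deterministic (time, then event key) so that
  repeated runs and different batchings export byte-identical tables.
* Batch ingestion through the CLI is all-or-nothing per batch: a file is
  fully parsed before any store mutation.

## Problem sizes

The test suite and acceptance script size their simulations for depth of
coverage at interactive run times: 20 independent 200-episode streams for
batching equivalence, 1,000 episodes per policy for oracle agreement,
2,000 episodes per probability level (p ∈ {0.5, 0.8, 0.95}) for
parameter recovery — enough that the 3·√(p(1−p)/n) recovery bound is a
few percentage points — and 100–150-episode cohorts for versioning and
consistency checks.  The parameter-recovery experiment fixes
`p_completion_recorded = 1`, `p_concurrent = 0`, `p_correction = 0` so
every scheduled interval is assessable and draws are independent across
episodes; these are the experiment's defining conditions, not tuning.

## Known limitations

* Cross-encounter matching and inference of missing Initiates are out of
  scope; a Complete preceding every Initiate of its encounter orphans.
* Concurrent-transfusion matching follows the latest-Initiate rule and
  can mis-assign a Complete between overlapping episodes; the ambiguity
  flag marks where this can happen, it does not resolve it.
* The generator does not emulate unstructured documentation, order-detail
  completeness, or inter-hospital vocabulary drift beyond what a
  `ColumnMap` rename covers.
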