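"""Synthetic EMR extract generator with ground truth.

Generates transfusion cohorts the way a transactional EMR would record
them: one long-format clinical-event row per data point (an Initiate row,
a Complete row, a consent acknowledgement, one row per vital-sign
reading), never a pre-joined transfusion row.  Real documentation defects
are emulated — missing completion records, partially documented
observation intervals, concurrent transfusions on one encounter sharing
observation rows, and retrospective corrections that supersede an earlier
row version via the ``UPDT_CNT`` counter.

Every emitted row is keyed back to the ground-truth episode that produced
it, and each episode carries true per-interval documentation flags.  Flags
are computed from the emitted rows themselves by direct window
containment, so they stay exact even when corrections move an initiation
time or concurrent episodes borrow each other's observations.  To keep the
per-interval Bernoulli draw equal to the resulting flag, observations for
one interval are placed only in the minutes of its window not covered by
any other interval's window set (schedule windows can overlap, e.g. the
post window and a late hourly window).

Determinism: a fixed config (including seed) yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal

import json

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .compliance import WindowPolicy
from .extract_io import ColumnMap, classify, format_timestamp, write_extract
from .records import Category, ClinicalEventRecord, Role

PRODUCT_TYPES = (
    "Red Blood Cells",
    "Platelets",
    "Fresh Frozen Plasma",
    "Cryoprecipitate",
    "Cryodepleted Plasma",
)
PRODUCT_WEIGHTS = (0.60, 0.15, 0.15, 0.05, 0.05)

MEDICAL_SERVICES = (
    "General Medicine",
    "Oncology",
    "Emergency",
    "Intensive Care",
    "Surgery",
)

Batching = Literal["monthly", "daily", "hourly", "single"]


class SimulationConfig(BaseModel):
    """Cohort parameters; defaults describe a plausible quarter of activity
    on a mid-size hospital network.

    ``p_obs_interval`` maps an interval id (``BASELINE``, ``MIN15``,
    ``HOURLY`` — applied to every required hourly subinterval — and
    ``POST``) to the probability that all four vital-sign categories are
    documented in that interval.
    """

    model_config = {"frozen": True}

    n_encounters: int = Field(default=120, gt=0)
    episodes_per_encounter_dist: dict[int, float] = Field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    duration_minutes_range: tuple[int, int] = (30, 300)
    p_obs_interval: dict[str, float] = Field(
        default_factory=lambda: {"BASELINE": 0.85, "MIN15": 0.75, "HOURLY": 0.80, "POST": 0.80}
    )
    p_consent: float = Field(default=0.90, ge=0.0, le=1.0)
    p_compatibility: float = Field(default=0.92, ge=0.0, le=1.0)
    p_completion_recorded: float = Field(default=0.85, ge=0.0, le=1.0)
    p_concurrent: float = Field(default=0.10, ge=0.0, le=1.0)
    p_correction: float = Field(default=0.05, ge=0.0, le=1.0)
    n_facilities: int = Field(default=3, gt=0)
    n_wards_per_facility: int = Field(default=2, gt=0)
    n_services: int = Field(default=4, gt=0, le=len(MEDICAL_SERVICES))
    time_span: tuple[datetime, datetime] = (datetime(2021, 11, 1), datetime(2022, 1, 31))
    seed: int = 0

    @field_validator("episodes_per_encounter_dist")
    @classmethod
    def _valid_dist(cls, v: dict[int, float]) -> dict[int, float]:
        if not v or not set(v) <= {1, 2, 3}:
            raise ValueError("episodes_per_encounter_dist keys must be within {1, 2, 3}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("episodes_per_encounter_dist must be a probability distribution")
        return v

    @field_validator("p_obs_interval")
    @classmethod
    def _valid_p_obs(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = {"BASELINE", "MIN15", "HOURLY", "POST"}
        bad = {k for k in v if k not in allowed and not k.startswith("HOURLY_")}
        if bad:
            raise ValueError(f"p_obs_interval has unknown interval ids: {sorted(bad)}")
        if any(not 0.0 <= p <= 1.0 for p in v.values()):
            raise ValueError("p_obs_interval probabilities must lie in [0, 1]")
        for key in ("BASELINE", "MIN15", "HOURLY", "POST"):
            v.setdefault(key, 0.8)
        return v

    @model_validator(mode="after")
    def _valid_span_and_duration(self) -> "SimulationConfig":
        lo, hi = self.duration_minutes_range
        if not (15 <= lo <= hi):
            raise ValueError("duration_minutes_range must satisfy 15 <= lo <= hi")
        start, end = self.time_span
        if end - start < timedelta(days=4):
            raise ValueError("time_span must cover at least 4 days")
        return self

    def p_for(self, interval_id: str) -> float:
        if interval_id in self.p_obs_interval:
            return self.p_obs_interval[interval_id]
        if interval_id.startswith("HOURLY"):
            return self.p_obs_interval["HOURLY"]
        raise KeyError(interval_id)


@dataclass(frozen=True)
class SimulatedRow:
    """An emitted raw row, its batch-assignment time and episode link.

    ``batch_time`` is when the row became visible to extraction: the event
    time for original rows, the correction time for superseding rows.
    """

    record: ClinicalEventRecord
    batch_time: datetime
    episode_id: str | None


@dataclass(frozen=True)
class TrueEpisode:
    episode_id: str
    encounter_id: str
    patient_id: str
    facility: str
    ward: str
    medical_service: str
    product_type: str
    start: datetime
    end: datetime
    completion_recorded: bool
    consent_documented: bool
    compatibility_documented: bool
    interval_documented: dict[str, bool] = field(default_factory=dict)
    required_hours: tuple[int, ...] = ()


@dataclass
class GroundTruth:
    config: SimulationConfig
    episodes: list[TrueEpisode]
    rows: list[SimulatedRow]

    @property
    def records(self) -> list[ClinicalEventRecord]:
        return [r.record for r in self.rows]


# ---------------------------------------------------------------------------
# window helpers (minute grid)

_MIN = timedelta(minutes=1)


def _window_minutes(lo: datetime, hi: datetime) -> list[datetime]:
    n = int((hi - lo) / _MIN)
    return [lo + i * _MIN for i in range(n + 1)]


def _in_any(t: datetime, windows: list[tuple[datetime, datetime]]) -> bool:
    return any(lo <= t <= hi for lo, hi in windows)


def _schedule_windows(
    start: datetime, end: datetime, t15: datetime | None, policy: WindowPolicy
) -> dict[str, list[tuple[datetime, datetime]]]:
    """Window map for a ground-truth episode (true end always known)."""
    g = policy.hourly_grace_min
    windows = {
        "BASELINE": [
            (start - timedelta(minutes=policy.baseline_before_min),
             start + timedelta(minutes=policy.baseline_after_min))
        ],
        "MIN15": [
            (start + timedelta(minutes=policy.t15_nominal_min - policy.t15_grace_min),
             start + timedelta(minutes=policy.t15_nominal_min + policy.t15_grace_min))
        ],
    }
    for k in range(1, policy.hourly_max_subintervals + 1):
        ws = [(start + timedelta(minutes=60 * k - g), start + timedelta(minutes=60 * k + g))]
        if t15 is not None:
            ws.append((t15 + timedelta(minutes=60 * k - g), t15 + timedelta(minutes=60 * k + g)))
        windows[f"HOURLY_{k}"] = ws
    windows["POST"] = [(end, end + timedelta(minutes=policy.post_window_min))]
    return windows


def _required_hours(start: datetime, end: datetime, policy: WindowPolicy) -> list[int]:
    return [
        k
        for k in range(1, policy.hourly_max_subintervals + 1)
        if end > start + timedelta(minutes=60 * k)
    ]


# ---------------------------------------------------------------------------
# value generators

def _obs_value(rng: np.random.Generator, form: str) -> str:
    if "Pulse" in form or "Heart" in form:
        return str(max(30, int(round(rng.normal(80, 12)))))
    if "Respiratory" in form:
        return str(max(6, int(round(rng.normal(17, 3)))))
    if "Temperature" in form:
        return f"{rng.normal(36.8, 0.4):.1f}"
    if "Systolic" in form:
        return str(max(60, int(round(rng.normal(120, 15)))))
    return str(max(35, int(round(rng.normal(75, 10)))))


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(config: SimulationConfig) -> GroundTruth:
    """Generate a ground-truth cohort and its raw event rows (version 1 only).

    Corrections are a separate step (:func:`inject_corrections`) so tests
    can exercise the pipeline with and without superseded versions.
    """
    rng = np.random.default_rng(config.seed)
    policy = WindowPolicy()
    cmap = ColumnMap()
    span_start, span_end = config.time_span
    span_minutes = int((span_end - span_start) / _MIN)

    facilities = [f"Hospital {chr(65 + i)}" for i in range(config.n_facilities)]
    wards = {
        f: [f"Ward {chr(65 + i)}{j + 1}" for j in range(config.n_wards_per_facility)]
        for i, f in enumerate(facilities)
    }
    services = list(MEDICAL_SERVICES[: config.n_services])
    ep_counts = sorted(config.episodes_per_encounter_dist)
    ep_probs = [config.episodes_per_encounter_dist[k] for k in ep_counts]

    rows: list[SimulatedRow] = []
    episodes: list[TrueEpisode] = []
    row_n = 0
    key_n = 0

    def emit(
        result_name: str,
        value: str,
        when: datetime,
        enc: str,
        pat: str,
        fac: str,
        ward: str,
        svc: str,
        episode_id: str | None,
    ) -> None:
        nonlocal row_n, key_n
        row_n += 1
        key_n += 1
        rec = ClinicalEventRecord(
            row_id=f"R{row_n:07d}",
            event_key=f"EV{key_n:07d}",
            patient_id=pat,
            encounter_id=enc,
            result_name=result_name,
            result_value=value,
            event_dt_tm=when,
            updt_cnt=1,
            facility=fac,
            ward=ward,
            medical_service=svc,
        )
        rows.append(SimulatedRow(rec, when, episode_id))

    for e in range(config.n_encounters):
        enc = f"E{e + 1:06d}"
        pat = f"P{e + 1:06d}"
        fac = facilities[int(rng.integers(len(facilities)))]
        wrd = wards[fac][int(rng.integers(len(wards[fac])))]
        svc = services[int(rng.integers(len(services)))]
        n_ep = int(rng.choice(ep_counts, p=ep_probs))

        lo_d, hi_d = config.duration_minutes_range
        first_start = span_start + timedelta(
            minutes=int(rng.integers(policy.baseline_before_min + 1, span_minutes - 4320))
        )
        prev_start = prev_end = None
        for i in range(n_ep):
            duration = int(rng.integers(lo_d, hi_d + 1))
            if prev_start is None:
                start = first_start
            elif rng.random() < config.p_concurrent and (prev_end - prev_start) > timedelta(minutes=20):
                offset = int(rng.integers(10, int((prev_end - prev_start) / _MIN) - 9))
                start = prev_start + timedelta(minutes=offset)
            else:
                start = prev_end + timedelta(minutes=int(rng.integers(60, 721)))
            end = start + timedelta(minutes=duration)
            prev_start, prev_end = start, end

            ep_id = f"T{len(episodes) + 1:05d}"
            product = str(rng.choice(PRODUCT_TYPES, p=PRODUCT_WEIGHTS))
            emit("Transfusion Initiate", product, start, enc, pat, fac, wrd, svc, ep_id)

            completion = bool(rng.random() < config.p_completion_recorded)
            if completion:
                emit("Transfusion Complete", product, end, enc, pat, fac, wrd, svc, ep_id)

            consent = bool(rng.random() < config.p_consent)
            if consent:
                when = start - timedelta(minutes=int(rng.integers(5, 1201)))
                emit("Blood Product Consent", "Consent sighted", when, enc, pat, fac, wrd, svc, ep_id)
            compat = bool(rng.random() < config.p_compatibility)
            if compat:
                when = start - timedelta(minutes=int(rng.integers(1, 31)))
                emit("Blood Compatibility Check", "Compatible", when, enc, pat, fac, wrd, svc, ep_id)

            _emit_observations(
                rng, config, policy, cmap, emit, start, end, enc, pat, fac, wrd, svc, ep_id
            )

            episodes.append(
                TrueEpisode(
                    episode_id=ep_id,
                    encounter_id=enc,
                    patient_id=pat,
                    facility=fac,
                    ward=wrd,
                    medical_service=svc,
                    product_type=product,
                    start=start,
                    end=end,
                    completion_recorded=completion,
                    consent_documented=consent,
                    compatibility_documented=compat,
                )
            )

    truth = GroundTruth(config=config, episodes=episodes, rows=rows)
    _recompute_truth_flags(truth, policy, cmap)
    return truth


def _emit_observations(
    rng, config, policy, cmap, emit, start, end, enc, pat, fac, wrd, svc, ep_id
) -> None:
    """Place vital-sign rows interval by interval in exclusive window zones."""
    # Phase 1: baseline and 15-minute intervals (windows independent of t15).
    windows = _schedule_windows(start, end, None, policy)
    t15: datetime | None = None
    for iv in ("BASELINE", "MIN15"):
        placed = _place_interval(rng, config, cmap, emit, iv, windows, {},
                                 enc, pat, fac, wrd, svc, ep_id)
        if iv == "MIN15" and placed:
            t15 = min(placed)

    # Phase 2: hourly and post, with windows anchored on the actual t15.
    windows = _schedule_windows(start, end, t15, policy)
    required = _required_hours(start, end, policy)
    exclusive_vs = {f"HOURLY_{k}": [f"HOURLY_{j}" for j in required if j != k] + ["POST"]
                    for k in required}
    exclusive_vs["POST"] = [f"HOURLY_{k}" for k in required]
    for iv in [f"HOURLY_{k}" for k in required] + ["POST"]:
        _place_interval(rng, config, cmap, emit, iv, windows, exclusive_vs,
                        enc, pat, fac, wrd, svc, ep_id)


def _place_interval(
    rng, config, cmap, emit, interval_id, windows, exclusive_vs,
    enc, pat, fac, wrd, svc, ep_id,
) -> list[datetime]:
    """Emit observation rows for one interval; return placed minutes.

    On a documented draw all four categories are emitted; otherwise a
    random strict subset.  Rows go into the interval's base window minus
    the windows of the intervals listed in ``exclusive_vs``.
    """
    documented = bool(rng.random() < config.p_for(interval_id))
    if documented:
        cats = list(Category)
    else:
        n_incl = int(rng.integers(0, len(Category)))
        cats = sorted(rng.choice([c.value for c in Category], size=n_incl, replace=False))
        cats = [Category(c) for c in cats]
    if not cats:
        return []

    base_lo, base_hi = windows[interval_id][0]
    excluded = [w for other in exclusive_vs.get(interval_id, ()) for w in windows[other]]
    zone = [t for t in _window_minutes(base_lo, base_hi) if not _in_any(t, excluded)]
    if not zone:  # cannot happen under the default schedule; stay safe
        zone = _window_minutes(base_lo, base_hi)

    placed: list[datetime] = []
    for cat in cats:
        when = zone[int(rng.integers(len(zone)))]
        placed.append(when)
        if cat is Category.BLOOD_PRESSURE:
            # systolic and diastolic are charted together
            for form in ("Systolic Blood Pressure", "Diastolic Blood Pressure"):
                emit(form, _obs_value(rng, form), when, enc, pat, fac, wrd, svc, ep_id)
        else:
            forms = cmap.forms_for(cat)
            form = str(rng.choice(forms))
            emit(form, _obs_value(rng, form), when, enc, pat, fac, wrd, svc, ep_id)
    return placed


# ---------------------------------------------------------------------------
# ground-truth flags by direct containment over the emitted rows

def _active_view(rows: list[SimulatedRow]) -> dict[str, ClinicalEventRecord]:
    best: dict[str, ClinicalEventRecord] = {}
    for r in rows:
        cur = best.get(r.record.event_key)
        if cur is None or r.record.updt_cnt > cur.updt_cnt:
            best[r.record.event_key] = r.record
    return best


def _recompute_truth_flags(truth: GroundTruth, policy: WindowPolicy, cmap: ColumnMap) -> None:
    """Recompute per-episode start/end and documentation flags from the
    highest-version emitted rows, by direct window containment."""
    active = _active_view(truth.rows)
    link: dict[str, dict[str, list[ClinicalEventRecord]]] = {}
    by_enc: dict[str, list[ClinicalEventRecord]] = {}
    for r in truth.rows:
        rec = active.get(r.record.event_key)
        if rec is None or rec.updt_cnt != r.record.updt_cnt:
            continue  # superseded version
        role, _ = classify(rec, cmap)
        if r.episode_id is not None and role in (Role.INITIATE, Role.COMPLETE):
            link.setdefault(r.episode_id, {}).setdefault(role.value, []).append(rec)
        by_enc.setdefault(rec.encounter_id, []).append(rec)

    for idx, ep in enumerate(truth.episodes):
        linked = link.get(ep.episode_id, {})
        start = linked["INITIATE"][0].event_dt_tm if linked.get("INITIATE") else ep.start
        duration = ep.end - ep.start
        if linked.get("COMPLETE"):
            end = linked["COMPLETE"][0].event_dt_tm
        elif start != ep.start:
            end = start + duration if not ep.completion_recorded else ep.end
        else:
            end = ep.end
        enc_rows = by_enc.get(ep.encounter_id, [])
        flags, consent, compat = _containment_flags(start, end, enc_rows, policy, cmap)
        truth.episodes[idx] = replace(
            ep,
            start=start,
            end=end,
            consent_documented=consent,
            compatibility_documented=compat,
            interval_documented=flags,
            required_hours=tuple(_required_hours(start, end, policy)),
        )


def _containment_flags(start, end, enc_rows, policy, cmap):
    span_lo = start - timedelta(minutes=policy.baseline_before_min)
    span_hi = end + timedelta(minutes=policy.post_window_min)
    obs = []
    consent = compat = False
    c_lo = start - timedelta(minutes=policy.consent_lookback_min)
    c_hi = start + timedelta(minutes=policy.baseline_after_min)
    for rec in enc_rows:
        role, cat = classify(rec, cmap)
        t = rec.event_dt_tm
        if role is Role.OBSERVATION and span_lo <= t <= span_hi:
            obs.append((cat, t))
        elif role is Role.CONSENT and c_lo <= t <= c_hi:
            consent = True
        elif role is Role.COMPATIBILITY and c_lo <= t <= c_hi:
            compat = True

    m_lo = start + timedelta(minutes=policy.t15_nominal_min - policy.t15_grace_min)
    m_hi = start + timedelta(minutes=policy.t15_nominal_min + policy.t15_grace_min)
    t15_times = [t for _, t in obs if m_lo <= t <= m_hi]
    t15 = min(t15_times) if t15_times else None
    windows = _schedule_windows(start, end, t15, policy)

    flags: dict[str, bool] = {}
    for iv in ["BASELINE", "MIN15"] + [f"HOURLY_{k}" for k in _required_hours(start, end, policy)] + ["POST"]:
        cats = {cat for cat, t in obs if _in_any(t, windows[iv])}
        flags[iv] = cats == set(Category)
    return flags, consent, compat


# ---------------------------------------------------------------------------
# corrections

def inject_corrections(truth: GroundTruth, p_correction: float, seed: int) -> GroundTruth:
    """Append superseding versions for a random subset of original rows.

    A corrected Initiate moves earlier and a corrected Complete moves later
    (charting lagged reality); other roles get a corrected value.  The new
    row keeps the logical event key, increments the version counter, gets a
    fresh row id, and is batch-assigned at its correction time.  Ground
    truth is recomputed so episodes reflect the corrected values.
    """
    if not 0.0 <= p_correction <= 1.0:
        raise ValueError("p_correction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cmap = ColumnMap()
    new_rows = list(truth.rows)
    for r in truth.rows:
        if r.record.updt_cnt != 1 or rng.random() >= p_correction:
            continue
        rec = r.record
        role, _ = classify(rec, cmap)
        when, value = rec.event_dt_tm, rec.result_value
        if role is Role.INITIATE:
            when = rec.event_dt_tm - timedelta(minutes=int(rng.integers(5, 46)))
        elif role is Role.COMPLETE:
            when = rec.event_dt_tm + timedelta(minutes=int(rng.integers(5, 46)))
        elif role is Role.OBSERVATION:
            value = _obs_value(rng, rec.result_name)
        else:
            value = rec.result_value + " (amended)"
        corrected = ClinicalEventRecord(
            row_id=f"{rec.row_id}C2",
            event_key=rec.event_key,
            patient_id=rec.patient_id,
            encounter_id=rec.encounter_id,
            result_name=rec.result_name,
            result_value=value,
            event_dt_tm=when,
            updt_cnt=rec.updt_cnt + 1,
            facility=rec.facility,
            ward=rec.ward,
            medical_service=rec.medical_service,
        )
        delay = timedelta(minutes=int(rng.integers(30, 2881)))
        new_rows.append(SimulatedRow(corrected, rec.event_dt_tm + delay, r.episode_id))

    out = GroundTruth(config=truth.config, episodes=list(truth.episodes), rows=new_rows)
    _recompute_truth_flags(out, WindowPolicy(), cmap)
    return out


def simulate(config: SimulationConfig) -> GroundTruth:
    """Full simulation: cohort plus corrections at ``config.p_correction``."""
    truth = simulate_cohort(config)
    if config.p_correction > 0:
        truth = inject_corrections(truth, config.p_correction, config.seed + 1)
    return truth


# ---------------------------------------------------------------------------
# batching and extract emission

def _batch_key(t: datetime, batching: Batching) -> str:
    if batching == "single":
        return "all"
    if batching == "monthly":
        return t.strftime("%Y-%m")
    if batching == "daily":
        return t.strftime("%Y-%m-%d")
    if batching == "hourly":
        return t.strftime("%Y-%m-%dT%H")
    raise ValueError(f"unknown batching mode: {batching!r}")


def partition_batches(
    truth: GroundTruth, batching: Batching
) -> list[tuple[str, list[ClinicalEventRecord]]]:
    """Partition rows into extract batches by batch-assignment time.

    The concatenation of all batches equals the full row set; a correction
    row lands in the batch of its correction time, which may differ from
    the batch of the original row.
    """
    _batch_key(datetime(2000, 1, 1), batching)  # validate mode up front
    batches: dict[str, list[tuple[datetime, ClinicalEventRecord]]] = {}
    for r in truth.rows:
        batches.setdefault(_batch_key(r.batch_time, batching), []).append(
            (r.batch_time, r.record)
        )
    out = []
    for key in sorted(batches):
        recs = [rec for _, rec in sorted(batches[key], key=lambda p: (p[0], p[1].row_id))]
        out.append((key, recs))
    return out


def emit_extracts(
    truth: GroundTruth, batching: Batching, out_dir: str | Path
) -> list[Path]:
    """Write one extract CSV per batch; returns the paths in batch order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for key, recs in partition_batches(truth, batching):
        paths.append(write_extract(recs, out_dir / f"extract_{key.replace(':', '')}.csv"))
    return paths


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Persist ground truth as JSON (test-harness use only)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "episodes": [
            {
                "episode_id": ep.episode_id,
                "encounter_id": ep.encounter_id,
                "patient_id": ep.patient_id,
                "facility": ep.facility,
                "ward": ep.ward,
                "medical_service": ep.medical_service,
                "product_type": ep.product_type,
                "start": format_timestamp(ep.start),
                "end": format_timestamp(ep.end),
                "completion_recorded": ep.completion_recorded,
                "consent_documented": ep.consent_documented,
                "compatibility_documented": ep.compatibility_documented,
                "interval_documented": ep.interval_documented,
                "required_hours": list(ep.required_hours),
            }
            for ep in truth.episodes
        ],
        "row_episode": {r.record.row_id: r.episode_id for r in truth.rows},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
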