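"""Rebuilding individual transfusion episodes from the active event set.

The EMR records a transfusion as disconnected clinical events — only the
Initiate row marks the start of a transfusion, and nothing links it to its
Complete row, its consent acknowledgement or the vital-sign observations
taken around it.  Reconstruction therefore:

* creates exactly one episode per active Initiate record;
* matches each Complete record, within its encounter, to the latest
  not-yet-matched Initiate at or before it (the only causally sound
  reading; ties broken by smallest event key), flagging ambiguity when
  more than one candidate existed — concurrent transfusions on the same
  patient are inherently unreliable to match;
* attaches consent/compatibility records found in a lookback window around
  the start, and every observation of the encounter inside the episode's
  assessment span.  Observations are measured on the patient, not on the
  blood product, so concurrent episodes share them.

Unmatchable Complete/consent/compatibility/observation records become
orphans — retained and reported, never dropped.

Incremental processing (:func:`apply_changeset`) rebuilds only the
encounters a changeset touched; its contract is strict equality with a
full :func:`build_episodes` over the same active set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from .compliance import WindowPolicy
from .extract_io import ColumnMap, classify
from .records import Category, ClinicalEventRecord, Role

OPEN = "OPEN"
CLOSED = "CLOSED"

Observation = tuple[Category, datetime, ClinicalEventRecord]


@dataclass(frozen=True)
class TransfusionEpisode:
    episode_id: str
    encounter_id: str
    patient_id: str
    initiate: ClinicalEventRecord
    complete: ClinicalEventRecord | None
    start_time: datetime
    end_time: datetime | None
    consent_event: ClinicalEventRecord | None
    compatibility_event: ClinicalEventRecord | None
    observations: tuple[Observation, ...]
    product_type: str
    facility: str
    ward: str
    medical_service: str
    status: str  # OPEN | CLOSED
    ambiguity_flag: bool = False


@dataclass(frozen=True)
class Orphan:
    record: ClinicalEventRecord
    reason: str


@dataclass(frozen=True)
class ReconstructionResult:
    episodes: tuple[TransfusionEpisode, ...]
    orphans: tuple[Orphan, ...]


def _mk_episode(initiate: ClinicalEventRecord) -> TransfusionEpisode:
    return TransfusionEpisode(
        episode_id=f"EP-{initiate.event_key}",
        encounter_id=initiate.encounter_id,
        patient_id=initiate.patient_id,
        initiate=initiate,
        complete=None,
        start_time=initiate.event_dt_tm,
        end_time=None,
        consent_event=None,
        compatibility_event=None,
        observations=(),
        product_type=initiate.result_value,
        facility=initiate.facility,
        ward=initiate.ward,
        medical_service=initiate.medical_service,
        status=OPEN,
    )


def match_complete(
    open_initiates: Sequence[TransfusionEpisode], complete: ClinicalEventRecord
) -> TransfusionEpisode | None:
    """Choose the episode a Complete record closes, or None.

    Candidates must share the encounter, be unmatched, and have started at
    or before the Complete.  The latest-starting candidate wins; ties break
    on the smallest initiate event key.
    """
    candidates = [
        ep
        for ep in open_initiates
        if ep.encounter_id == complete.encounter_id
        and ep.complete is None
        and ep.start_time <= complete.event_dt_tm
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda ep: (ep.start_time, _neg_key(ep.initiate.event_key)))


class _neg_key(str):
    """Reverse lexicographic ordering so max() prefers the smallest key."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _attach_single(
    episode: TransfusionEpisode,
    events: Sequence[ClinicalEventRecord],
    lookback_min: int,
    after_min: int,
) -> ClinicalEventRecord | None:
    """Latest record within [start - lookback, start + after]; tie → smallest key."""
    lo = episode.start_time - timedelta(minutes=lookback_min)
    hi = episode.start_time + timedelta(minutes=after_min)
    qualifying = [e for e in events if lo <= e.event_dt_tm <= hi]
    if not qualifying:
        return None
    return max(qualifying, key=lambda e: (e.event_dt_tm, _neg_key(e.event_key)))


def attach_observations(
    episode: TransfusionEpisode,
    encounter_events: Sequence[ClinicalEventRecord],
    policy: WindowPolicy,
    column_map: ColumnMap | None = None,
) -> TransfusionEpisode:
    """Attach consent, compatibility and every in-span observation.

    The observation span runs from ``start - baseline_before`` to the
    assessment horizon: ``end + post_window`` for closed episodes, else
    ``start + 60 * hourly_max + post_window``.  Shared observations may
    attach to several concurrent episodes.
    """
    cmap = column_map or ColumnMap()
    consents, compats, observations = [], [], []
    for e in encounter_events:
        role, cat = classify(e, cmap)
        if role is Role.CONSENT:
            consents.append(e)
        elif role is Role.COMPATIBILITY:
            compats.append(e)
        elif role is Role.OBSERVATION:
            observations.append((cat, e))

    consent = _attach_single(episode, consents, policy.consent_lookback_min, policy.baseline_after_min)
    compat = _attach_single(episode, compats, policy.consent_lookback_min, policy.baseline_after_min)

    lo = episode.start_time - timedelta(minutes=policy.baseline_before_min)
    if episode.end_time is not None:
        hi = episode.end_time + timedelta(minutes=policy.post_window_min)
    else:
        hi = episode.start_time + timedelta(minutes=policy.assessment_horizon_min())
    attached = tuple(
        sorted(
            ((cat, e.event_dt_tm, e) for cat, e in observations if lo <= e.event_dt_tm <= hi),
            key=lambda o: (o[1], o[2].event_key),
        )
    )
    return replace(
        episode,
        consent_event=consent,
        compatibility_event=compat,
        observations=attached,
    )


def build_episodes(
    active: Iterable[ClinicalEventRecord],
    policy: WindowPolicy | None = None,
    column_map: ColumnMap | None = None,
) -> ReconstructionResult:
    """One-shot reconstruction of all episodes from the active event set."""
    policy = policy or WindowPolicy()
    cmap = column_map or ColumnMap()

    by_encounter: dict[str, list[ClinicalEventRecord]] = {}
    for rec in active:
        by_encounter.setdefault(rec.encounter_id, []).append(rec)

    episodes: list[TransfusionEpisode] = []
    orphans: list[Orphan] = []
    for enc in sorted(by_encounter):
        eps, orp = _build_encounter(by_encounter[enc], policy, cmap)
        episodes.extend(eps)
        orphans.extend(orp)

    episodes.sort(key=lambda ep: (ep.start_time, ep.episode_id))
    orphans.sort(key=lambda o: (o.record.event_dt_tm, o.record.event_key))
    return ReconstructionResult(tuple(episodes), tuple(orphans))


def _build_encounter(
    events: Sequence[ClinicalEventRecord], policy: WindowPolicy, cmap: ColumnMap
) -> tuple[list[TransfusionEpisode], list[Orphan]]:
    events = sorted(events, key=lambda r: (r.event_dt_tm, r.event_key))
    initiates, completes, others = [], [], []
    for e in events:
        role, _ = classify(e, cmap)
        if role is Role.INITIATE:
            initiates.append(e)
        elif role is Role.COMPLETE:
            completes.append(e)
        elif role is not Role.OTHER:
            others.append(e)

    episodes = [_mk_episode(i) for i in initiates]
    orphans: list[Orphan] = []

    # Match each Complete, in time order, to the latest unmatched Initiate.
    for comp in completes:
        chosen = match_complete(episodes, comp)
        if chosen is None:
            orphans.append(Orphan(comp, "unmatched-complete"))
            continue
        n_candidates = sum(
            1
            for ep in episodes
            if ep.complete is None and ep.start_time <= comp.event_dt_tm
        )
        idx = episodes.index(chosen)
        episodes[idx] = replace(
            chosen,
            complete=comp,
            end_time=comp.event_dt_tm,
            status=CLOSED,
            ambiguity_flag=chosen.ambiguity_flag or n_candidates > 1,
        )

    episodes = [attach_observations(ep, others, policy, cmap) for ep in episodes]

    # Records that attached to no episode are orphans.
    attached_keys: set[str] = set()
    for ep in episodes:
        if ep.consent_event is not None:
            attached_keys.add(ep.consent_event.event_key)
        if ep.compatibility_event is not None:
            attached_keys.add(ep.compatibility_event.event_key)
        attached_keys.update(o[2].event_key for o in ep.observations)
    reason = {
        Role.CONSENT: "unattached-consent",
        Role.COMPATIBILITY: "unattached-compatibility",
        Role.OBSERVATION: "unattached-observation",
    }
    for e in others:
        if e.event_key not in attached_keys:
            role, _ = classify(e, cmap)
            orphans.append(Orphan(e, reason[role]))
    return episodes, orphans


def apply_changeset(
    previous: ReconstructionResult,
    changeset,
    active: Iterable[ClinicalEventRecord],
    policy: WindowPolicy | None = None,
    column_map: ColumnMap | None = None,
) -> ReconstructionResult:
    """Incrementally update a reconstruction after an upsert.

    Only the encounters the changeset touched are rebuilt; all other
    episodes and orphans carry over.  The result is identical to a full
    ``build_episodes(active)`` — incrementality is an optimization, never
    a semantic change.
    """
    if changeset.is_empty():
        return previous
    policy = policy or WindowPolicy()
    cmap = column_map or ColumnMap()
    touched = changeset.touched_encounters

    kept_eps = [ep for ep in previous.episodes if ep.encounter_id not in touched]
    kept_orp = [o for o in previous.orphans if o.record.encounter_id not in touched]

    by_encounter: dict[str, list[ClinicalEventRecord]] = {}
    for rec in active:
        if rec.encounter_id in touched:
            by_encounter.setdefault(rec.encounter_id, []).append(rec)

    for enc in sorted(by_encounter):
        eps, orp = _build_encounter(by_encounter[enc], policy, cmap)
        kept_eps.extend(eps)
        kept_orp.extend(orp)

    kept_eps.sort(key=lambda ep: (ep.start_time, ep.episode_id))
    kept_orp.sort(key=lambda o: (o.record.event_dt_tm, o.record.event_key))
    return ReconstructionResult(tuple(kept_eps), tuple(kept_orp))
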