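"""Versioned store of active clinical events across extract batches.

The EMR never destroys a corrected record: it appends a new row with the
same logical event key and an incremented version counter (``UPDT_CNT``).
This store keeps, for every event key, the highest-version record seen so
far (*active*), an append-only log of records that were replaced
(*superseded*), and a log of stale deliveries (lower-or-equal versions
arriving late).  Superseded and stale records never reach downstream
computation.

Upserts are order-insensitive: since versions are totally ordered per key,
any permutation of batches converges to the same active set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .extract_io import ColumnMap, classify
from .records import ClinicalEventRecord, Role

logger = logging.getLogger(__name__)


class VersionConflictError(ValueError):
    """Two records share (event_key, updt_cnt) but carry different payloads."""


@dataclass
class Changeset:
    """What one upsert changed, for incremental downstream processing."""

    inserted: dict[str, ClinicalEventRecord] = field(default_factory=dict)
    replaced: dict[str, tuple[ClinicalEventRecord, ClinicalEventRecord]] = field(
        default_factory=dict
    )
    stale: list[ClinicalEventRecord] = field(default_factory=list)

    @property
    def changed_keys(self) -> set[str]:
        return set(self.inserted) | set(self.replaced)

    @property
    def touched_encounters(self) -> set[str]:
        """Encounters whose event set changed (old and new encounter of a
        replaced record, in case a correction moved it)."""
        enc = {r.encounter_id for r in self.inserted.values()}
        for old, new in self.replaced.values():
            enc.add(old.encounter_id)
            enc.add(new.encounter_id)
        return enc

    def is_empty(self) -> bool:
        return not self.inserted and not self.replaced


def dedupe_within_batch(records: Sequence[ClinicalEventRecord]) -> list[ClinicalEventRecord]:
    """Keep only the highest version of each event key within one batch.

    Identical redeliveries (same key, version and payload) collapse to one
    row.  Same (key, version) with a different payload is a hard error: the
    source can never legitimately produce that.
    Output order follows the first appearance of each surviving key.
    """
    best: dict[str, ClinicalEventRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.event_key)
        if cur is None:
            best[rec.event_key] = rec
            order.append(rec.event_key)
        elif rec.updt_cnt > cur.updt_cnt:
            best[rec.event_key] = rec
        elif rec.updt_cnt == cur.updt_cnt and not rec.same_payload(cur):
            raise VersionConflictError(
                f"event {rec.event_key} v{rec.updt_cnt}: conflicting payloads in one batch"
            )
    return [best[k] for k in order]


class EventStore:
    """Active / superseded / stale partition of all ingested rows.

    Conservation invariant: every record ever passed to :meth:`upsert`
    (post within-batch dedupe) is in exactly one of the three partitions.
    """

    def __init__(self) -> None:
        self.active: dict[str, ClinicalEventRecord] = {}
        self.superseded: list[ClinicalEventRecord] = []
        self.stale_discarded: list[ClinicalEventRecord] = []
        self.n_upserted = 0

    # -- ingestion -------------------------------------------------------

    def upsert(self, records: Iterable[ClinicalEventRecord]) -> Changeset:
        """Apply a deduped batch; return the changeset of keys that changed.

        Higher version replaces the active record (replacement logged to the
        superseded log); lower or equal version is discarded as a stale
        delivery — logged, never an error, so out-of-order batches converge.
        """
        cs = Changeset()
        for rec in records:
            self.n_upserted += 1
            cur = self.active.get(rec.event_key)
            if cur is None:
                self.active[rec.event_key] = rec
                cs.inserted[rec.event_key] = rec
            elif rec.updt_cnt > cur.updt_cnt:
                self.active[rec.event_key] = rec
                self.superseded.append(cur)
                cs.replaced[rec.event_key] = (cur, rec)
            elif rec.updt_cnt == cur.updt_cnt and not rec.same_payload(cur):
                raise VersionConflictError(
                    f"event {rec.event_key} v{rec.updt_cnt}: payload differs from active record"
                )
            else:
                logger.debug("stale delivery discarded: %s v%d", rec.event_key, rec.updt_cnt)
                self.stale_discarded.append(rec)
                cs.stale.append(rec)
        return cs

    # -- queries ---------------------------------------------------------

    def active_events(
        self,
        *,
        encounter_ids: Iterable[str] | None = None,
        roles: Iterable[Role] | None = None,
        column_map: ColumnMap | None = None,
        start: "object" = None,
        end: "object" = None,
        predicate: Callable[[ClinicalEventRecord], bool] | None = None,
    ) -> list[ClinicalEventRecord]:
        """Active records matching the filters, sorted by (time, event_key)."""
        recs = self.active.values()
        if encounter_ids is not None:
            wanted = set(encounter_ids)
            recs = (r for r in recs if r.encounter_id in wanted)
        if roles is not None:
            cmap = column_map or ColumnMap()
            wanted_roles = set(roles)
            recs = (r for r in recs if classify(r, cmap)[0] in wanted_roles)
        if start is not None:
            recs = (r for r in recs if r.event_dt_tm >= start)
        if end is not None:
            recs = (r for r in recs if r.event_dt_tm <= end)
        if predicate is not None:
            recs = (r for r in recs if predicate(r))
        return sorted(recs, key=lambda r: (r.event_dt_tm, r.event_key))

    # -- invariants ------------------------------------------------------

    def conserved(self) -> bool:
        """|upserted| == |active| + |superseded| + |stale| at all times."""
        return self.n_upserted == (
            len(self.active) + len(self.superseded) + len(self.stale_discarded)
        )
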