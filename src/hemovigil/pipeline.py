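"""End-to-end ETL orchestration: read → dedupe → upsert → reconstruct →
score → aggregate, with SQLite persistence.

This is the glue the command-line interface and the test harness share.
Reconstruction is updated incrementally from each upsert's changeset;
compliance flags and warehouse tables are recomputed lazily, so ingesting
many small batches stays cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .compliance import ComplianceResult, WindowPolicy, evaluate_episode
from .event_store import EventStore, dedupe_within_batch
from .extract_io import ColumnMap, read_extract
from .reconstruction import (
    CLOSED,
    OPEN,
    ReconstructionResult,
    apply_changeset,
    build_episodes,
)
from . import warehouse as wh


@dataclass(frozen=True)
class IngestSummary:
    batch_id: str
    rows_read: int
    rejects: int
    dedupe_dropped: int
    inserted: int
    replaced: int
    stale: int
    episodes_open: int
    episodes_closed: int
    orphans: int

    def changed(self) -> int:
        return self.inserted + self.replaced


class Pipeline:
    """Stateful warehouse maintainer over any batching frequency."""

    def __init__(self, column_map: ColumnMap | None = None, policy: WindowPolicy | None = None):
        self.column_map = column_map or ColumnMap()
        self.policy = policy or WindowPolicy()
        self.store = EventStore()
        self.result = ReconstructionResult((), ())
        self.rejects: list = []
        self._cache: dict[str, object] = {}

    # -- ingestion -------------------------------------------------------

    def ingest_records(self, records, batch_id: str = "", n_rejects: int = 0) -> IngestSummary:
        deduped = dedupe_within_batch(records)
        changeset = self.store.upsert(deduped)
        self.result = apply_changeset(
            self.result, changeset, self.store.active.values(), self.policy, self.column_map
        )
        if not changeset.is_empty():
            self._cache.clear()
        return IngestSummary(
            batch_id=batch_id,
            rows_read=len(records),
            rejects=n_rejects,
            dedupe_dropped=len(records) - len(deduped),
            inserted=len(changeset.inserted),
            replaced=len(changeset.replaced),
            stale=len(changeset.stale),
            episodes_open=sum(ep.status == OPEN for ep in self.result.episodes),
            episodes_closed=sum(ep.status == CLOSED for ep in self.result.episodes),
            orphans=len(self.result.orphans),
        )

    def ingest_file(self, path: str | Path) -> IngestSummary:
        """All-or-nothing: the file is fully read and validated before any
        store mutation; an unreadable file aborts with no state change."""
        records, rejects = read_extract(path, self.column_map)
        self.rejects.extend(rejects)
        return self.ingest_records(records, batch_id=Path(path).stem, n_rejects=len(rejects))

    # -- derived tables (lazy) -------------------------------------------

    def compliance_results(self) -> list[ComplianceResult]:
        if "results" not in self._cache:
            self._cache["results"] = [
                evaluate_episode(ep, self.policy) for ep in self.result.episodes
            ]
        return self._cache["results"]  # type: ignore[return-value]

    def transfusions(self) -> pd.DataFrame:
        if "transfusions" not in self._cache:
            self._cache["transfusions"] = wh.transfusion_table(
                self.result.episodes,
                self.compliance_results(),
                hourly_max=self.policy.hourly_max_subintervals,
            )
        return self._cache["transfusions"]  # type: ignore[return-value]

    def daily_facts(self) -> pd.DataFrame:
        if "facts" not in self._cache:
            self._cache["facts"] = wh.aggregate_daily(self.transfusions())
        return self._cache["facts"]  # type: ignore[return-value]

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        orphans = pd.DataFrame(
            [
                {"EVENT_KEY": o.record.event_key, "RESULT_NAME": o.record.result_name,
                 "EVENT_DT_TM": o.record.event_dt_tm.strftime("%Y-%m-%dT%H:%M"),
                 "ENCNTR_ID": o.record.encounter_id, "REASON": o.reason}
                for o in self.result.orphans
            ],
            columns=["EVENT_KEY", "RESULT_NAME", "EVENT_DT_TM", "ENCNTR_ID", "REASON"],
        )
        wh.save_tables(
            path,
            {
                "ACTIVE_EVENTS": wh.events_frame(self.store.active.values()),
                "SUPERSEDED_EVENTS": wh.events_frame(self.store.superseded),
                "STALE_EVENTS": wh.events_frame(self.store.stale_discarded),
                "TRANSFUSION": self.transfusions(),
                "TRANSFUSION_DAILY_FACT": self.daily_facts(),
                "ORPHAN_EVENTS": orphans,
            },
        )

    @classmethod
    def load(
        cls,
        path: str | Path,
        column_map: ColumnMap | None = None,
        policy: WindowPolicy | None = None,
    ) -> "Pipeline":
        tables = wh.load_tables(path)
        pipe = cls(column_map=column_map, policy=policy)
        for rec in wh.frame_to_records(tables.get("ACTIVE_EVENTS", pd.DataFrame(columns=wh.EVENT_COLUMNS))):
            pipe.store.active[rec.event_key] = rec
        pipe.store.superseded = wh.frame_to_records(
            tables.get("SUPERSEDED_EVENTS", pd.DataFrame(columns=wh.EVENT_COLUMNS))
        )
        pipe.store.stale_discarded = wh.frame_to_records(
            tables.get("STALE_EVENTS", pd.DataFrame(columns=wh.EVENT_COLUMNS))
        )
        pipe.store.n_upserted = (
            len(pipe.store.active) + len(pipe.store.superseded) + len(pipe.store.stale_discarded)
        )
        pipe.result = build_episodes(
            pipe.store.active_events(), pipe.policy, pipe.column_map
        )
        return pipe
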