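"""Episode reconstruction: Complete matching, attachment, incremental equivalence."""

from datetime import timedelta

import pytest

from hemovigil import (
    EventStore,
    Pipeline,
    SimulationConfig,
    apply_changeset,
    build_episodes,
    dedupe_within_batch,
    inject_corrections,
    partition_batches,
    simulate_cohort,
)
from hemovigil.reconstruction import CLOSED, OPEN

from helpers import at, full_interval, rec


def _build(records, policy, cmap):
    return build_episodes(records, policy, cmap)


class TestCompleteMatching:
    def test_unique_pair_closes_episode(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(10), key="I1"),
                rec("Transfusion Complete", at(12), key="C1"),
            ],
            policy,
            cmap,
        )
        (ep,) = res.episodes
        assert ep.status == CLOSED and ep.end_time == at(12)
        assert res.orphans == ()

    def test_complete_without_initiate_is_orphan(self, policy, cmap):
        res = _build([rec("Transfusion Complete", at(12), key="C1")], policy, cmap)
        assert res.episodes == ()
        assert [o.reason for o in res.orphans] == ["unmatched-complete"]

    def test_complete_matches_latest_initiate_and_flags_ambiguity(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(10), key="I1"),
                rec("Transfusion Initiate", at(11), key="I2"),
                rec("Transfusion Complete", at(12), key="C1"),
            ],
            policy,
            cmap,
        )
        by_key = {ep.initiate.event_key: ep for ep in res.episodes}
        assert by_key["I2"].status == CLOSED and by_key["I2"].end_time == at(12)
        assert by_key["I2"].ambiguity_flag is True
        assert by_key["I1"].status == OPEN and by_key["I1"].ambiguity_flag is False

    def test_initiate_after_complete_excluded(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(12), key="I1"),
                rec("Transfusion Complete", at(11), key="C1"),
            ],
            policy,
            cmap,
        )
        (ep,) = res.episodes
        assert ep.status == OPEN
        assert [o.reason for o in res.orphans] == ["unmatched-complete"]

    def test_simultaneous_initiates_tie_broken_by_smallest_key(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(10), key="IB"),
                rec("Transfusion Initiate", at(10), key="IA"),
                rec("Transfusion Complete", at(11), key="C1"),
            ],
            policy,
            cmap,
        )
        closed = [ep for ep in res.episodes if ep.status == CLOSED]
        assert [ep.initiate.event_key for ep in closed] == ["IA"]

    def test_cross_encounter_matching_never_happens(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(10), key="I1", encounter="E1"),
                rec("Transfusion Complete", at(12), key="C1", encounter="E2"),
            ],
            policy,
            cmap,
        )
        (ep,) = res.episodes
        assert ep.status == OPEN
        assert [o.reason for o in res.orphans] == ["unmatched-complete"]

    def test_two_completes_close_two_episodes_in_order(self, policy, cmap):
        res = _build(
            [
                rec("Transfusion Initiate", at(9), key="I1"),
                rec("Transfusion Initiate", at(10), key="I2"),
                rec("Transfusion Complete", at(11), key="C1"),
                rec("Transfusion Complete", at(12), key="C2"),
            ],
            policy,
            cmap,
        )
        ends = {ep.initiate.event_key: ep.end_time for ep in res.episodes}
        # first Complete takes the latest initiate (10:00); second takes 09:00
        assert ends == {"I2": at(11), "I1": at(12)}


class TestAttachment:
    def test_observation_inside_span_attached_boundary_included(self, policy, cmap):
        events = [
            rec("Transfusion Initiate", at(10), key="I1"),
            rec("Transfusion Complete", at(12), key="C1"),
            rec("Heart Rate", at(9, 30), key="O1"),     # start - 30 min
            rec("Heart Rate", at(9, 0), key="O2"),      # exactly start - 60
            rec("Heart Rate", at(13, 0), key="O3"),     # exactly end + 60
            rec("Heart Rate", at(13, 1), key="O4"),     # beyond horizon
        ]
        res = _build(events, policy, cmap)
        (ep,) = res.episodes
        attached = {o[2].event_key for o in ep.observations}
        assert attached == {"O1", "O2", "O3"}
        assert [o.record.event_key for o in res.orphans] == ["O4"]

    def test_consent_attaches_within_lookback_not_as_observation(self, policy, cmap):
        events = [
            rec("Transfusion Initiate", at(10), key="I1"),
            rec("Blood Product Consent", at(8), key="CS1"),  # start - 2 h
        ]
        res = _build(events, policy, cmap)
        (ep,) = res.episodes
        assert ep.consent_event is not None and ep.consent_event.event_key == "CS1"
        assert ep.observations == ()

    def test_consent_older_than_lookback_is_orphan(self, policy, cmap):
        events = [
            rec("Transfusion Initiate", at(10, 0, day=3), key="I1"),
            rec("Blood Product Consent", at(9, 59, day=2), key="CS1"),  # 24h 1min before
        ]
        res = _build(events, policy, cmap)
        (ep,) = res.episodes
        assert ep.consent_event is None
        assert [o.reason for o in res.orphans] == ["unattached-consent"]

    def test_shared_observation_attaches_to_both_concurrent_episodes(self, policy, cmap):
        events = [
            rec("Transfusion Initiate", at(10), key="I1"),
            rec("Transfusion Initiate", at(11), key="I2"),
            rec("Heart Rate", at(10, 30), key="O1"),  # between both starts
        ]
        res = _build(events, policy, cmap)
        for ep in res.episodes:
            assert [o[2].event_key for o in ep.observations] == ["O1"]

    def test_open_episode_horizon_bounds_attachment(self, policy, cmap):
        # no Complete: horizon = start + 60*3 + 60 = start + 4 h
        events = [
            rec("Transfusion Initiate", at(10), key="I1"),
            rec("Heart Rate", at(14, 0), key="O1"),   # exactly at horizon
            rec("Heart Rate", at(14, 1), key="O2"),   # past horizon
        ]
        res = _build(events, policy, cmap)
        (ep,) = res.episodes
        assert [o[2].event_key for o in ep.observations] == ["O1"]


class TestApplyChangeset:
    def _pipeline_vs_rebuild(self, batches, policy, cmap):
        store = EventStore()
        from hemovigil.reconstruction import ReconstructionResult

        incremental = ReconstructionResult((), ())
        for batch in batches:
            cs = store.upsert(dedupe_within_batch(batch))
            incremental = apply_changeset(incremental, cs, store.active.values(), policy, cmap)
        full = build_episodes(store.active_events(), policy, cmap)
        return incremental, full

    def test_late_complete_closes_open_episode(self, policy, cmap):
        b1 = [rec("Transfusion Initiate", at(10), key="I1")]
        b2 = [rec("Transfusion Complete", at(12), key="C1")]
        inc, full = self._pipeline_vs_rebuild([b1, b2], policy, cmap)
        assert inc == full
        assert inc.episodes[0].status == CLOSED

    def test_corrected_initiate_moves_start_and_reattributes(self, policy, cmap):
        initiate_v1 = rec("Transfusion Initiate", at(10), key="I1", updt_cnt=1)
        obs = rec("Heart Rate", at(8, 45), key="O1")  # outside window of 10:00 start
        b1 = [initiate_v1, obs]
        initiate_v2 = rec(
            "Transfusion Initiate", at(9, 30), key="I1", updt_cnt=2, row_id="I1.v2"
        )
        inc, full = self._pipeline_vs_rebuild([b1, [initiate_v2]], policy, cmap)
        assert inc == full
        (ep,) = inc.episodes
        assert ep.start_time == at(9, 30)
        assert [o[2].event_key for o in ep.observations] == ["O1"]

    def test_empty_changeset_returns_previous_object(self, policy, cmap):
        b1 = [rec("Transfusion Initiate", at(10), key="I1")]
        store = EventStore()
        cs = store.upsert(dedupe_within_batch(b1))
        first = apply_changeset(
            build_episodes((), policy, cmap), cs, store.active.values(), policy, cmap
        )
        cs2 = store.upsert(dedupe_within_batch(b1))  # all stale
        second = apply_changeset(first, cs2, store.active.values(), policy, cmap)
        assert second is first

    @pytest.mark.parametrize("batching", ["hourly", "daily", "monthly"])
    def test_incremental_equals_one_shot_on_simulated_stream(self, policy, cmap, batching):
        """Folding changesets over any batching equals a single rebuild."""
        truth = inject_corrections(
            simulate_cohort(SimulationConfig(n_encounters=30, seed=11)), 0.2, seed=12
        )
        batches = [recs for _, recs in partition_batches(truth, batching)]
        inc, full = self._pipeline_vs_rebuild(batches, policy, cmap)
        assert inc == full
        n_initiates = sum(1 for r in full.episodes)
        assert n_initiates == len(
            [r for r in EventStoreFromTruth(truth).values() if r.result_name == "Transfusion Initiate"]
        )


def EventStoreFromTruth(truth):
    best = {}
    for r in truth.rows:
        cur = best.get(r.record.event_key)
        if cur is None or r.record.updt_cnt > cur.updt_cnt:
            best[r.record.event_key] = r.record
    return best
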