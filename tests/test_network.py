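"""Network-burst grouping, merging, leaders and the precedence graph."""

import numpy as np
import pytest

from meaburst.bursts import detect_bursts_fixed
from meaburst.core import Burst, NetworkBurst
from meaburst.network import (
    NetworkBurstParams,
    detect_network_bursts_adaptive,
    detect_network_bursts_fixed,
    identify_leaders,
    merge_network_bursts,
    network_graph,
    write_edge_list,
)
from meaburst.synthetic import gen_network_recording


def _bursts_by_unit(onsets_by_unit, length=0.3, n_spikes=5):
    return {
        uid: [Burst(uid, s, s + length, n_spikes) for s in starts]
        for uid, starts in onsets_by_unit.items()
    }


def brute_force_groups(onsets, max_ibei):
    """Independent run enumeration over a sorted onset sequence."""
    groups, current = [], []
    for t in onsets:
        if current and t - current[-1] > max_ibei:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return groups


class TestFixedDetection:
    def test_five_units_forced_group(self):
        bby = _bursts_by_unit({u: [0.05 * u] for u in range(5)})
        nbs = detect_network_bursts_fixed(bby, 0.2, 5)
        assert len(nbs) == 1
        assert nbs[0].n_units == 5
        assert nbs[0].start == 0.0 and nbs[0].end == pytest.approx(0.5)
        assert nbs[0].n_spikes == 25

    def test_below_min_units_no_event(self):
        bby = _bursts_by_unit({u: [0.05 * u] for u in range(4)})
        assert detect_network_bursts_fixed(bby, 0.2, 5) == []

    def test_two_separated_groups(self):
        bby = _bursts_by_unit({u: [0.05 * u, 10.0 + 0.05 * u] for u in range(5)})
        nbs = detect_network_bursts_fixed(bby, 0.2, 5)
        assert len(nbs) == 2

    def test_matches_brute_force_grouping(self, rng):
        for _ in range(200):
            n_units = int(rng.integers(2, 6))
            bby = {
                uid: [
                    Burst(uid, s, s + 0.05, 5)
                    for s in np.sort(rng.uniform(0, 10, rng.integers(0, 8)))
                ]
                for uid in range(n_units)
            }
            max_ibei = float(rng.uniform(0.05, 1.0))
            pooled = sorted(
                (b for bs in bby.values() for b in bs), key=lambda b: b.start
            )
            expected = [
                g
                for g in brute_force_groups([b.start for b in pooled], max_ibei)
                if len({b.unit_id for b in pooled if b.start in g}) >= 2
            ]
            nbs = detect_network_bursts_fixed(bby, max_ibei, min_units=2)
            assert len(nbs) == len(expected)
            for nb, group in zip(nbs, expected):
                assert nb.start == pytest.approx(min(group))

    def test_repeated_unit_counts_once_with_earliest_onset(self):
        bby = _bursts_by_unit({0: [0.0, 0.1], 1: [0.05], 2: [0.15]})
        nbs = detect_network_bursts_fixed(bby, 0.2, 3)
        assert len(nbs) == 1
        assert nbs[0].n_units == 3
        assert nbs[0].onsets[0] == 0.0


class TestAdaptiveDetection:
    def test_recovers_generated_events_and_threshold(self):
        rec, truth = gen_network_recording(
            n_units=10, nb_rate=0.5, lag=0.020, jitter_sd=0.005, duration=120.0, seed=4
        )
        bby = {u: detect_bursts_fixed(rec.trains[u], 0.1, 5) for u in rec.unit_ids}
        nbs, hist = detect_network_bursts_adaptive(bby, NetworkBurstParams())
        assert hist.threshold is not None
        assert 0.04 <= hist.threshold <= 1.0
        assert len(nbs) == len(truth)

    def test_unimodal_ibeis_fall_back_to_fixed(self):
        # regular lone-ish bursts: one IBEI mode, no valley
        rng = np.random.default_rng(0)
        starts = np.cumsum(rng.uniform(0.9, 1.1, 60))
        bby = {
            uid: [Burst(uid, s, s + 0.05, 5) for s in starts[uid::3]]
            for uid in range(3)
        }
        nbs, hist = detect_network_bursts_adaptive(
            bby, NetworkBurstParams(min_units=2)
        )
        assert hist is None or hist.threshold is None
        assert nbs == detect_network_bursts_fixed(bby, 0.2, 2)

    def test_single_unit_never_forms_event(self):
        bby = _bursts_by_unit({0: list(np.arange(20) * 0.1)})
        nbs, _ = detect_network_bursts_adaptive(bby, NetworkBurstParams())
        assert nbs == []


class TestMerging:
    def _nb(self, start, end, uids):
        onsets = {u: start + 0.01 * i for i, u in enumerate(uids)}
        return NetworkBurst(start, end, frozenset(uids), onsets, uids[0], 10)

    def test_close_events_merge(self):
        nbs = [self._nb(0.0, 1.0, [1, 2]), self._nb(1.005, 2.0, [2, 3])]
        merged = merge_network_bursts(nbs, 0.01)
        assert len(merged) == 1
        assert merged[0].start == 0.0 and merged[0].end == 2.0
        assert merged[0].participants == {1, 2, 3}
        assert merged[0].n_spikes == 20

    def test_negative_separation_disables_merging(self):
        nbs = [self._nb(0.0, 1.0, [1, 2]), self._nb(1.005, 2.0, [2, 3])]
        assert merge_network_bursts(nbs, -0.01) == nbs

    def test_overlap_merges_at_zero_separation(self):
        nbs = [self._nb(0.0, 1.0, [1, 2]), self._nb(0.8, 2.0, [3, 4])]
        assert len(merge_network_bursts(nbs, 0.0)) == 1

    def test_merging_idempotent(self, rng):
        for _ in range(50):
            starts = np.sort(rng.uniform(0, 20, 8))
            nbs = [self._nb(s, s + rng.uniform(0.1, 1.0), [1, 2]) for s in starts]
            once = merge_network_bursts(nbs, 0.2)
            assert merge_network_bursts(once, 0.2) == once


class TestLeaders:
    def test_minimal_onset_leads(self):
        nb = NetworkBurst(0.0, 1.0, frozenset({1, 3}), {3: 0.00, 1: 0.01}, 3, 10)
        counts = identify_leaders([nb])
        assert counts[3]["n_led"] == 1 and counts[1]["n_led"] == 0

    def test_led_counts_sum_to_event_count(self, rng):
        nbs = []
        for i in range(10):
            uids = list(rng.choice(20, size=5, replace=False))
            onsets = {int(u): float(i + rng.uniform(0, 0.1)) for u in uids}
            leader = min(onsets, key=lambda u: (onsets[u], u))
            nbs.append(
                NetworkBurst(i, i + 0.5, frozenset(onsets), onsets, leader, 25)
            )
        counts = identify_leaders(nbs)
        assert sum(c["n_led"] for c in counts.values()) == 10

    def test_designated_leader_recovered(self):
        rec, truth = gen_network_recording(
            n_units=15, nb_rate=0.1, leader=4, lag=0.020, jitter_sd=0.005,
            duration=400.0, seed=11,
        )
        bby = {u: detect_bursts_fixed(rec.trains[u], 0.1, 5) for u in rec.unit_ids}
        nbs = detect_network_bursts_fixed(bby, 0.2, 5)
        assert len(nbs) == len(truth) > 0
        counts = identify_leaders(nbs)
        assert counts[4]["n_led"] / len(nbs) >= 0.8


class TestNetworkGraph:
    def test_onset_order_edges(self):
        nb = NetworkBurst(
            0.0, 1.0, frozenset({1, 2, 3}), {3: 0.0, 1: 0.1, 2: 0.2}, 3, 15
        )
        edges = network_graph([nb])
        assert edges == {(3, 1): 1, (3, 2): 1, (1, 2): 1}

    def test_edge_count_is_pairs(self):
        k = 6
        onsets = {u: 0.01 * u for u in range(k)}
        nb = NetworkBurst(0.0, 1.0, frozenset(onsets), onsets, 0, 30)
        edges = network_graph([nb])
        assert sum(edges.values()) == k * (k - 1) // 2

    def test_leader_out_weight(self):
        onsets = {u: 0.01 * u for u in range(5)}
        nb = NetworkBurst(0.0, 1.0, frozenset(onsets), onsets, 0, 25)
        edges = network_graph([nb])
        assert sum(w for (u, _), w in edges.items() if u == 0) == 4

    def test_tied_onsets_contribute_no_edge(self):
        nb = NetworkBurst(0.0, 1.0, frozenset({1, 2}), {1: 0.0, 2: 0.0}, 1, 10)
        assert network_graph([nb]) == {}

    def test_no_self_edges_and_integer_weights(self, rng):
        rec, _ = gen_network_recording(n_units=8, nb_rate=0.1, duration=200.0, seed=3)
        bby = {u: detect_bursts_fixed(rec.trains[u], 0.1, 5) for u in rec.unit_ids}
        edges = network_graph(detect_network_bursts_fixed(bby, 0.2, 5))
        for (u, v), w in edges.items():
            assert u != v
            assert isinstance(w, int) and w > 0

    def test_edge_list_round_trip(self, tmp_path):
        edges = {(3, 1): 2, (1, 2): 1}
        path = tmp_path / "edges.tsv"
        write_edge_list(edges, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert set(lines[1:]) == {"3\t1\t2", "1\t2\t1"}
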