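"""Network-burst detection, merging, leaders, and the precedence graph.

A network burst is near-simultaneous bursting of at least a minimum number
of distinct units.  Per-unit bursts are pooled and sorted by onset; runs of
onsets whose successive inter-burst-event intervals (IBEIs) stay within a
threshold form candidate events.  The threshold is either fixed (default
0.2 s) or derived adaptively from the valley of the log10 IBEI histogram,
mirroring the per-unit logISI method.  The burst *leader* of an event is the
participant with the earliest burst onset; ordered onset pairs accumulate
into a directed precedence graph whose edge weights count how often one unit
preceded another inside a network burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bursts import InsufficientDataError, find_isi_threshold, log_interval_histogram
from .core import Burst, ISIHistogram, NetworkBurst

__all__ = [
    "NetworkBurstParams",
    "detect_network_bursts_fixed",
    "detect_network_bursts_adaptive",
    "merge_network_bursts",
    "identify_leaders",
    "network_graph",
    "write_edge_list",
]


@dataclass(frozen=True)
class NetworkBurstParams:
    """Network-burst parameter set with the standard defaults.

    ``min_separation < 0`` disables post-detection merging.  The adaptive
    IBEI threshold is uncapped by default (``max_ibei_threshold = None``).
    """

    max_ibei: float = 0.2         # s
    min_units: int = 5
    min_separation: float = -0.01  # s; negative disables merging
    max_intra_peak: float = 0.2   # s
    bin_size: float = 0.1
    smooth_window: int = 3
    smooth_order: int = 1
    peak_min_distance: int = 2
    min_void: float = 0.5
    max_ibei_threshold: float | None = None


def _pool_bursts(bursts_by_unit: dict[int, list[Burst]]) -> list[Burst]:
    pooled = [b for bursts in bursts_by_unit.values() for b in bursts]
    pooled.sort(key=lambda b: (b.start, b.unit_id))
    return pooled


def _group_to_network_bursts(
    pooled: list[Burst], max_ibei: float, min_units: int
) -> list[NetworkBurst]:
    """Group maximal onset runs with successive IBEIs <= max_ibei."""
    events: list[NetworkBurst] = []
    group: list[Burst] = []

    def flush(group: list[Burst]) -> None:
        units = {b.unit_id for b in group}
        if len(units) < min_units:
            return
        onsets: dict[int, float] = {}
        for b in group:  # pooled order: earliest burst of each unit wins
            onsets.setdefault(b.unit_id, b.start)
        leader = min(onsets, key=lambda u: (onsets[u], u))
        events.append(
            NetworkBurst(
                start=min(b.start for b in group),
                end=max(b.end for b in group),
                participants=frozenset(units),
                onsets=onsets,
                leader=leader,
                n_spikes=sum(b.n_spikes for b in group),
            )
        )

    for b in pooled:
        if group and b.start - group[-1].start > max_ibei:
            flush(group)
            group = []
        group.append(b)
    if group:
        flush(group)
    return events


def detect_network_bursts_fixed(
    bursts_by_unit: dict[int, list[Burst]],
    max_ibei: float = 0.2,
    min_units: int = 5,
) -> list[NetworkBurst]:
    """Fixed-threshold network-burst detection over pooled burst onsets."""
    if max_ibei <= 0:
        raise ValueError("max_ibei must be > 0")
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    pooled = _pool_bursts(bursts_by_unit)
    return _group_to_network_bursts(pooled, max_ibei, min_units)


def detect_network_bursts_adaptive(
    bursts_by_unit: dict[int, list[Burst]],
    params: NetworkBurstParams = NetworkBurstParams(),
) -> tuple[list[NetworkBurst], ISIHistogram | None]:
    """Adaptive network-burst detection via the log IBEI histogram valley.

    The IBEI threshold is found on the pooled onset-to-onset interval
    sequence with the same valley search as the per-unit logISI method
    (intra-event peak below ``max_intra_peak``, void >= ``min_void``); when
    no threshold qualifies the fixed defaults are used.
    """
    pooled = _pool_bursts(bursts_by_unit)
    hist: ISIHistogram | None = None
    threshold: float | None = None
    if len(pooled) >= 3:
        ibeis = np.diff([b.start for b in pooled])
        try:
            hist = log_interval_histogram(
                ibeis, params.bin_size, params.smooth_window, params.smooth_order
            )
            threshold = find_isi_threshold(
                hist,
                params.max_intra_peak,
                params.min_void,
                params.peak_min_distance,
                params.max_ibei_threshold,
            )
        except InsufficientDataError:
            pass
    max_ibei = threshold if threshold is not None else params.max_ibei
    return _group_to_network_bursts(pooled, max_ibei, params.min_units), hist


def merge_network_bursts(
    nbs: list[NetworkBurst], min_separation: float = -0.01
) -> list[NetworkBurst]:
    """Merge consecutive events separated by <= ``min_separation`` seconds.

    Applied transitively; participants are unioned, each unit keeps its
    earliest onset, spike counts are summed.  A negative ``min_separation``
    disables merging (the input is returned unchanged).
    """
    if min_separation < 0 or not nbs:
        return list(nbs)
    merged = [nbs[0]]
    for nb in nbs[1:]:
        prev = merged[-1]
        if nb.start - prev.end <= min_separation:
            onsets = dict(prev.onsets)
            for uid, onset in nb.onsets.items():
                if uid not in onsets or onset < onsets[uid]:
                    onsets[uid] = onset
            leader = min(onsets, key=lambda u: (onsets[u], u))
            merged[-1] = NetworkBurst(
                start=min(prev.start, nb.start),
                end=max(prev.end, nb.end),
                participants=prev.participants | nb.participants,
                onsets=onsets,
                leader=leader,
                n_spikes=prev.n_spikes + nb.n_spikes,
            )
        else:
            merged.append(nb)
    return merged


def identify_leaders(nbs: list[NetworkBurst]) -> dict[int, dict[str, int]]:
    """Per-unit counts of network bursts led and participated in.

    The leader of each event is the participant with the minimal burst
    onset (ties break toward the smaller unit id), so summed ``n_led``
    equals the number of events.
    """
    counts: dict[int, dict[str, int]] = {}
    for nb in nbs:
        for uid in nb.participants:
            entry = counts.setdefault(uid, {"n_led": 0, "n_participated": 0})
            entry["n_participated"] += 1
        counts[nb.leader]["n_led"] += 1
    return counts


def network_graph(nbs: list[NetworkBurst]) -> dict[tuple[int, int], int]:
    """Directed precedence graph: weight(u, v) counts events where u's onset
    preceded v's.  Equal onsets contribute no edge; there are no self-edges."""
    edges: dict[tuple[int, int], int] = {}
    for nb in nbs:
        items = sorted(nb.onsets.items(), key=lambda kv: (kv[1], kv[0]))
        for i, (u, tu) in enumerate(items):
            for v, tv in items[i + 1 :]:
                if tu < tv:
                    edges[(u, v)] = edges.get((u, v), 0) + 1
    return edges


def write_edge_list(edges: dict[tuple[int, int], int], path) -> None:
    """Write the precedence graph as a tab-separated ``u v weight`` file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in sorted(edges.items()):
            fh.write(f"{u}\t{v}\t{w}\n")
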