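"""Per-unit burst detection: fixed-threshold, adaptive logISI, and hybrid.

Three detectors are provided:

* **fixed** — group maximal runs of spikes whose successive inter-spike
  intervals (ISIs) stay within a fixed ``max_isi``; a run with at least
  ``min_spikes`` spikes is a burst.  Two parameters, no adaptation.
* **adaptive** — derive a per-unit ISI threshold from the valley of the
  log10 ISI histogram separating the intra-burst mode from the inter-burst
  mode (the logISI method).  Small thresholds are used directly; large ones
  drive a two-stage search that finds tight burst cores and extends them
  outward over slower boundary spikes.
* **hybrid** — the adaptive threshold plugged straight into the fixed
  grouping rule.

All interval comparisons are inclusive (an ISI exactly equal to the
threshold joins the burst).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import Burst, ISIHistogram, SpikeTrain

__all__ = [
    "BurstParams",
    "detect_bursts_fixed",
    "log_isi_histogram",
    "log_interval_histogram",
    "find_isi_threshold",
    "detect_bursts_adaptive",
    "detect_bursts_hybrid",
    "burst_metrics",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few intervals to build a histogram."""


@dataclass(frozen=True)
class BurstParams:
    """Burst-detection parameter set with the standard defaults.

    ``max_isi`` is the fixed method's grouping threshold and the adaptive
    method's fallback; ``isi_choice`` decides whether an adaptive threshold
    is applied directly or via core extension; ``max_isi_threshold`` caps
    adaptive thresholds (larger values trigger the fixed fallback).  The
    histogram parameters control the logISI valley search.
    """

    max_isi: float = 0.1          # s
    min_spikes: int = 5
    max_isi_threshold: float = 1.0  # s, adaptive cap
    isi_choice: float = 0.1       # s, algorithm-choice parameter
    max_intra_peak: float = 0.1   # s, intra-burst peak must lie below this
    bin_size: float = 0.1         # log10 decades
    smooth_window: int = 3        # bins
    smooth_order: int = 1         # polynomial order
    peak_min_distance: int = 2    # bins
    min_void: float = 0.7


def _runs_within(times: np.ndarray, max_isi: float) -> list[tuple[int, int]]:
    """Maximal runs [i, j] of spike indices with all successive ISIs <= max_isi."""
    if times.size < 2:
        return []
    ok = np.diff(times) <= max_isi
    runs: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(ok):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, len(ok)))
    return runs


def detect_bursts_fixed(
    train: SpikeTrain, max_isi: float = 0.1, min_spikes: int = 5
) -> list[Burst]:
    """Fixed-threshold burst detection (two parameters).

    Returns ordered, non-overlapping bursts; each burst spans from its first
    to its last spike.
    """
    if max_isi <= 0:
        raise ValueError("max_isi must be > 0")
    if min_spikes < 2:
        raise ValueError("min_spikes must be >= 2")
    t = train.times
    return [
        Burst(train.unit_id, t[i], t[j], j - i + 1)
        for i, j in _runs_within(t, max_isi)
        if j - i + 1 >= min_spikes
    ]


def log_interval_histogram(
    intervals: np.ndarray,
    bin_size: float = 0.1,
    smooth_window: int = 3,
    smooth_order: int = 1,
) -> ISIHistogram:
    """Log10 histogram of positive intervals (given in seconds, binned in ms).

    Bins have uniform width ``bin_size`` decades with edges snapped to
    multiples of ``bin_size``, spanning the floor/ceil decades of the
    smallest and largest interval.  Counts are smoothed with a
    Savitzky-Golay (local least-squares polynomial) filter and clipped at
    zero; fewer bins than the window leaves the counts unsmoothed.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if smooth_window % 2 == 0 or smooth_window <= smooth_order:
        raise ValueError("smooth_window must be odd and > smooth_order")
    intervals = np.asarray(intervals, dtype=float)
    intervals = intervals[intervals > 0]
    if intervals.size < 2:
        raise InsufficientDataError("need at least 2 positive intervals")
    # snap away binary-float noise so equal decimal intervals share a bin
    log_ms = np.round(np.log10(intervals * 1000.0), 12)
    lo = np.floor(log_ms.min())
    hi = np.ceil(log_ms.max())
    if hi <= lo:
        hi = lo + 1.0
    n_bins = int(round((hi - lo) / bin_size))
    edges = lo + np.arange(n_bins + 1) * bin_size
    counts, _ = np.histogram(log_ms, bins=edges)
    if len(counts) >= smooth_window:
        smoothed = savgol_filter(
            counts.astype(float), smooth_window, smooth_order, mode="interp"
        )
        smoothed = np.clip(smoothed, 0.0, None)
    else:
        smoothed = counts.astype(float)
    return ISIHistogram(bin_edges=edges, counts=counts, smoothed=smoothed)


def log_isi_histogram(
    train: SpikeTrain,
    bin_size: float = 0.1,
    smooth_window: int = 3,
    smooth_order: int = 1,
) -> ISIHistogram:
    """Log10 ISI histogram of one spike train (see :func:`log_interval_histogram`)."""
    if train.n_spikes < 3:
        raise InsufficientDataError("need at least 3 spikes (2 intervals)")
    return log_interval_histogram(train.isis(), bin_size, smooth_window, smooth_order)


def find_isi_threshold(
    hist: ISIHistogram,
    max_intra_peak: float = 0.1,
    min_void: float = 0.7,
    peak_min_distance: int = 2,
    max_threshold: float | None = 1.0,
) -> float | None:
    """Adaptive interval threshold from the logISI valley search.

    Peaks of the smoothed histogram (minimum index separation
    ``peak_min_distance``) are searched for an intra-burst peak: the highest
    peak at an interval <= ``max_intra_peak`` seconds.  For every later peak
    the void parameter

        v = 1 - h(m) / sqrt(h(p1) * h(p2))

    scores the depth of the interior minimum ``m`` between the peak pair.
    The threshold is the interval at the smallest-interval minimum whose
    void reaches ``min_void``; ``None`` (fallback signal) when there is no
    intra-burst peak, no qualifying void, or the threshold would exceed
    ``max_threshold``.  Peak indices, void values and the threshold are also
    recorded on ``hist``.
    """
    smoothed = hist.smoothed
    peaks, _ = find_peaks(smoothed, distance=max(1, peak_min_distance))
    hist.peaks = peaks
    hist.voids = {}
    hist.threshold = None
    if peaks.size < 2:
        return None

    centers_ms = 10.0 ** hist.bin_centers
    intra_candidates = peaks[centers_ms[peaks] <= max_intra_peak * 1000.0]
    if intra_candidates.size == 0:
        return None
    # highest smoothed value wins; ties break toward the smaller interval
    p1 = int(intra_candidates[np.argmax(smoothed[intra_candidates])])

    best_m: int | None = None
    for p2 in peaks[peaks > p1]:
        interior = np.arange(p1 + 1, p2)
        if interior.size == 0:
            continue
        # flat valleys: take the central bin of the minimal plateau
        low = interior[smoothed[interior] == smoothed[interior].min()]
        m = int(low[low.size // 2])
        denom = np.sqrt(smoothed[p1] * smoothed[p2])
        if denom == 0:
            continue
        void = 1.0 - smoothed[m] / denom
        hist.voids[(p1, int(p2))] = float(void)
        if void >= min_void and (best_m is None or m < best_m):
            best_m = m
    if best_m is None:
        return None
    threshold = float(centers_ms[best_m] / 1000.0)
    if max_threshold is not None and threshold > max_threshold:
        return None
    hist.threshold = threshold
    return threshold


def _extend_and_merge_cores(
    times: np.ndarray,
    core_runs: list[tuple[int, int]],
    extend_isi: float,
) -> list[tuple[int, int]]:
    """Extend burst cores outward over gaps <= extend_isi; merge overlaps."""
    isis = np.diff(times)
    extended: list[tuple[int, int]] = []
    for i, j in core_runs:
        while i > 0 and isis[i - 1] <= extend_isi:
            i -= 1
        while j < len(times) - 1 and isis[j] <= extend_isi:
            j += 1
        extended.append((i, j))
    merged: list[tuple[int, int]] = []
    for i, j in extended:
        if merged and i <= merged[-1][1]:  # share at least one spike
            merged[-1] = (merged[-1][0], max(merged[-1][1], j))
        else:
            merged.append((i, j))
    return merged


def detect_bursts_adaptive(
    train: SpikeTrain, params: BurstParams = BurstParams()
) -> tuple[list[Burst], ISIHistogram | None]:
    """logISI adaptive burst detection with fixed-threshold fallback.

    The per-unit threshold ``T`` from :func:`find_isi_threshold` selects one
    of three regimes: (i) no threshold — fall back to the fixed method with
    the default ``max_isi``; (ii) ``T <= isi_choice`` — fixed method with
    ``max_isi = T``; (iii) ``T > isi_choice`` — find tight burst cores with
    the choice threshold, extend each core outward over adjacent spikes
    whose gap is within ``T``, and merge cores that touch.  ``min_spikes``
    applies to the final bursts in every regime.
    """
    hist: ISIHistogram | None = None
    threshold: float | None = None
    try:
        hist = log_isi_histogram(
            train, params.bin_size, params.smooth_window, params.smooth_order
        )
        threshold = find_isi_threshold(
            hist,
            params.max_intra_peak,
            params.min_void,
            params.peak_min_distance,
            params.max_isi_threshold,
        )
    except InsufficientDataError:
        pass

    if threshold is None:
        return detect_bursts_fixed(train, params.max_isi, params.min_spikes), hist
    if threshold <= params.isi_choice:
        return detect_bursts_fixed(train, threshold, params.min_spikes), hist

    t = train.times
    cores = _runs_within(t, params.isi_choice)
    merged = _extend_and_merge_cores(t, cores, threshold)
    bursts = [
        Burst(train.unit_id, t[i], t[j], j - i + 1)
        for i, j in merged
        if j - i + 1 >= params.min_spikes
    ]
    return bursts, hist


def detect_bursts_hybrid(
    train: SpikeTrain, params: BurstParams = BurstParams()
) -> list[Burst]:
    """Adaptive logISI threshold applied through the fixed grouping rule."""
    threshold: float | None = None
    try:
        hist = log_isi_histogram(
            train, params.bin_size, params.smooth_window, params.smooth_order
        )
        threshold = find_isi_threshold(
            hist,
            params.max_intra_peak,
            params.min_void,
            params.peak_min_distance,
            params.max_isi_threshold,
        )
    except InsufficientDataError:
        pass
    max_isi = threshold if threshold is not None else params.max_isi
    return detect_bursts_fixed(train, max_isi, params.min_spikes)


def burst_metrics(
    bursts: list[Burst], duration: float | None = None
) -> tuple[list[dict], dict | None]:
    """Per-burst duration (s) and density (Hz) plus a summary.

    Density is spikes per second within the burst; bursts of zero duration
    (all spikes coincident) carry ``density = NaN`` and are excluded from
    the summary statistics.  The summary holds the mean and SD of duration
    and density, and — when the recording ``duration`` is given — the burst
    rate in bursts per second.  An empty burst list yields an empty metric
    list and no summary.
    """
    per_burst = [
        {
            "unit_id": b.unit_id,
            "start": b.start,
            "end": b.end,
            "n_spikes": b.n_spikes,
            "duration": b.duration,
            "density": b.density,
        }
        for b in bursts
    ]
    if not per_burst:
        return per_burst, None
    durations = np.array([m["duration"] for m in per_burst])
    densities = np.array([m["density"] for m in per_burst])
    densities = densities[np.isfinite(densities)]
    summary = {
        "n_bursts": len(per_burst),
        "mean_duration": float(durations.mean()),
        "sd_duration": float(durations.std(ddof=0)),
        "mean_density": float(densities.mean()) if densities.size else float("nan"),
        "sd_density": float(densities.std(ddof=0)) if densities.size else float("nan"),
    }
    if duration is not None:
        summary["burst_rate"] = len(per_burst) / duration
    return per_burst, summary
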