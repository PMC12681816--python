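"""Active-unit selection, ISI-violation quality filtering, and binned rates.

Spike-sorted units are admitted to analysis when their mean firing rate
reaches a minimum (default 0.05 Hz), and optionally when their refractory
contamination — estimated by the inter-spike-interval violation ratio — stays
below a ceiling.  All boundary comparisons are inclusive.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Recording, SpikeTrain

__all__ = [
    "firing_rate",
    "select_active_units",
    "isi_violation_ratio",
    "filter_by_isi_violations",
    "common_active_units",
    "binned_rate",
]


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate in Hz: spike count over recording duration."""
    return train.n_spikes / train.duration


def select_active_units(recording: Recording, min_rate: float = 0.05) -> set[int]:
    """Units whose firing rate is at least ``min_rate`` Hz (inclusive)."""
    if min_rate < 0:
        raise ValueError("min_rate must be >= 0")
    return {
        uid for uid, train in recording.trains.items() if firing_rate(train) >= min_rate
    }


def isi_violation_ratio(train: SpikeTrain, t_ref: float = 0.0015) -> float:
    """Refractory-contamination estimate from short inter-spike intervals.

    Counts consecutive-spike intervals shorter than the refractory threshold
    ``t_ref`` (seconds) and scales the count against the rate expected by
    chance for an uncorrelated contaminating process:

        ratio = C * T / (2 * N^2 * t_ref)

    with C the violation count, N the number of spikes and T the recording
    duration.  A ratio near 0 marks a well-isolated unit; values >= 1 suggest
    heavy contamination.  Trains with fewer than two spikes return 0.
    """
    if t_ref <= 0:
        raise ValueError("t_ref must be > 0")
    n = train.n_spikes
    if n < 2:
        return 0.0
    violations = int(np.count_nonzero(train.isis() < t_ref))
    return violations * train.duration / (2.0 * n * n * t_ref)


def filter_by_isi_violations(
    recording: Recording, max_ratio: float = 0.0, t_ref: float = 0.0015
) -> set[int]:
    """Units with violation ratio <= ``max_ratio``; 0 disables the filter."""
    if max_ratio < 0:
        raise ValueError("max_ratio must be >= 0")
    if max_ratio == 0:
        return set(recording.trains)
    return {
        uid
        for uid, train in recording.trains.items()
        if isi_violation_ratio(train, t_ref) <= max_ratio
    }


def common_active_units(
    recordings: list[Recording], mode: str = "all", min_rate: float = 0.05
) -> set[int]:
    """Units active (rate >= ``min_rate``) in every / at least one recording.

    ``mode="all"`` intersects the per-recording active sets, ``mode="any"``
    unions them; unit ids must be comparable across recordings.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    if not recordings:
        raise ValueError("need at least one recording")
    sets = [select_active_units(rec, min_rate) for rec in recordings]
    return set.intersection(*sets) if mode == "all" else set.union(*sets)


def binned_rate(event_times, bin_size: float, duration: float) -> np.ndarray:
    """Event rate per time bin in Hz; the final partial bin is width-normalized.

    Used for the average firing / bursting / network-bursting rate timelines
    (defaults 5, 10 and 20 s bins respectively).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n_bins = max(1, math.ceil(duration / bin_size))
    edges = np.minimum(np.arange(n_bins + 1) * bin_size, duration)
    counts, _ = np.histogram(np.asarray(event_times, dtype=float), bins=edges)
    widths = np.diff(edges)
    return counts / widths
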