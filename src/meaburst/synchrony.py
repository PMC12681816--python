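"""Pairwise spike-train synchrony measures.

Three complementary measures are implemented:

* :func:`sttc` — the spike-time tiling coefficient, a firing-rate-robust
  correlation in [-1, 1] based on the fraction of each train's spikes that
  fall within ±dt of the other train's spikes, corrected by the fraction of
  the recording tiled by those windows.
* :func:`spike_distance` — the ISI-distance: the time-averaged absolute
  ratio deviation of the two trains' instantaneous inter-spike intervals;
  0 for identical trains, larger for dissimilar ones.
* :func:`phase_synchrony` — the mean resultant length of the phase
  differences between the trains, with each train's phase advancing by 2π
  per inter-spike interval; 1 for phase-locked trains, near 0 for
  independent ones.  Parameter-free.

Undefined results (empty or too-short trains, degenerate denominators) are
returned as NaN so the all-pairs matrix can flag them without raising.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor

import numpy as np

from .core import DIAGONAL_VALUE, Recording, SpikeTrain, SynchronyMatrix

__all__ = ["sttc", "spike_distance", "phase_synchrony", "pairwise_matrix"]


def _tiling_fraction(times: np.ndarray, dt: float, duration: float) -> float:
    """Fraction of [0, duration] within ±dt of a spike (windows unioned)."""
    starts = np.clip(times - dt, 0.0, duration)
    ends = np.clip(times + dt, 0.0, duration)
    # spikes are sorted, so consecutive windows can only overlap pairwise
    overlap = np.clip(ends[:-1] - starts[1:], 0.0, None)
    return float((np.sum(ends - starts) - np.sum(overlap)) / duration)


def _near_fraction(x: np.ndarray, y: np.ndarray, dt: float) -> float:
    """Fraction of x's spikes within dt (inclusive) of some spike of y."""
    idx = np.searchsorted(y, x)
    d_right = np.where(idx < y.size, y[np.minimum(idx, y.size - 1)] - x, np.inf)
    d_left = np.where(idx > 0, x - y[np.maximum(idx - 1, 0)], np.inf)
    return float(np.mean(np.minimum(d_left, d_right) <= dt))


def sttc(a: SpikeTrain, b: SpikeTrain, dt: float = 0.5) -> float:
    """Spike-time tiling coefficient with window half-width ``dt`` seconds.

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

    where T_X is the fraction of the recording tiled by ±dt windows around
    X's spikes and P_X the fraction of X's spikes within dt of any spike of
    the other train.  Identical trains score 1; NaN when a train is empty or
    a denominator vanishes.
    """
    if a.n_spikes == 0 or b.n_spikes == 0:
        return float("nan")
    if a.duration != b.duration:
        raise ValueError("trains must share the recording duration")
    duration = a.duration
    t_a = _tiling_fraction(a.times, dt, duration)
    t_b = _tiling_fraction(b.times, dt, duration)
    p_a = _near_fraction(a.times, b.times, dt)
    p_b = _near_fraction(b.times, a.times, dt)
    if p_a * t_b == 1.0 or p_b * t_a == 1.0:
        return float("nan")
    return 0.5 * ((p_a - t_b) / (1.0 - p_a * t_b) + (p_b - t_a) / (1.0 - p_b * t_a))


def _current_isi(aug: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Length of the augmented-train interval containing each sample time."""
    idx = np.searchsorted(aug, t, side="right") - 1
    idx = np.clip(idx, 0, aug.size - 2)
    return aug[idx + 1] - aug[idx]


def spike_distance(a: SpikeTrain, b: SpikeTrain, n_bin: int = 120) -> float:
    """ISI-distance sampled at ``n_bin`` equally spaced times.

    Each train is augmented with auxiliary edge events at 0 and the
    recording end; at each sample time the instantaneous inter-spike
    intervals I_A, I_B give a signed ratio r = I_A/I_B - 1 (when
    I_A <= I_B, else mirrored); the distance is the mean of |r|.  Identical
    trains score exactly 0.
    """
    if n_bin < 1:
        raise ValueError("n_bin must be >= 1")
    if a.n_spikes == 0 or b.n_spikes == 0:
        return float("nan")
    if a.duration != b.duration:
        raise ValueError("trains must share the recording duration")
    duration = a.duration
    aug_a = np.unique(np.concatenate([[0.0], a.times, [duration]]))
    aug_b = np.unique(np.concatenate([[0.0], b.times, [duration]]))
    # sample at bin midpoints to avoid landing on the edge events
    t = (np.arange(n_bin) + 0.5) * duration / n_bin
    i_a = _current_isi(aug_a, t)
    i_b = _current_isi(aug_b, t)
    lo = np.minimum(i_a, i_b)
    hi = np.maximum(i_a, i_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(hi > 0, 1.0 - lo / hi, 0.0)
    return float(np.mean(r))


def _phase(times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linearly interpolated phase 2π(k + fraction) between spikes k, k+1."""
    k = np.searchsorted(times, t, side="right") - 1
    k = np.clip(k, 0, times.size - 2)
    isi = times[k + 1] - times[k]
    frac = np.where(isi > 0, (t - times[k]) / np.where(isi > 0, isi, 1.0), 0.0)
    return 2.0 * np.pi * (k + frac)


def _resultant_length(a: SpikeTrain, b: SpikeTrain) -> float:
    """Mean resultant length of phase differences sampled at a's spikes."""
    tb = np.unique(b.times)
    ta = np.unique(a.times)
    sample = ta[(ta >= tb[0]) & (ta <= tb[-1])]
    if sample.size == 0:
        return float("nan")
    dphi = _phase(ta, sample) - _phase(tb, sample)
    return float(np.hypot(np.mean(np.cos(dphi)), np.mean(np.sin(dphi))))


def phase_synchrony(a: SpikeTrain, b: SpikeTrain) -> float:
    """Parameter-free phase-locking measure in [0, 1].

    Phase differences are sampled at each train's spike times within the
    other train's spiking span and summarized by the mean resultant length;
    the two directed values are averaged so the measure is symmetric.
    Trains with fewer than two distinct spikes return NaN.
    """
    if len(np.unique(a.times)) < 2 or len(np.unique(b.times)) < 2:
        return float("nan")
    r_ab = _resultant_length(a, b)
    r_ba = _resultant_length(b, a)
    return 0.5 * (r_ab + r_ba)


_METHODS = {
    "sttc": lambda a, b, p: sttc(a, b, **p),
    "spike_distance": lambda a, b, p: spike_distance(a, b, **p),
    "phase_synchrony": lambda a, b, p: phase_synchrony(a, b),
}


def _pair_value(args):
    a, b, method, params = args
    return _METHODS[method](a, b, params)


def pairwise_matrix(
    recording: Recording,
    unit_ids: list[int] | None = None,
    method: str = "sttc",
    params: dict | None = None,
    n_processes: int = 1,
) -> SynchronyMatrix:
    """All-pairs synchrony matrix for one method and parameter set.

    The matrix is symmetric with the method's identity value on the
    diagonal (1 for sttc and phase synchrony, 0 for spike distance);
    undefined pairs are NaN.  ``n_processes`` only distributes the pair
    computations — the result is identical for any value.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    params = dict(params or {})
    if unit_ids is None:
        unit_ids = recording.unit_ids
    missing = [u for u in unit_ids if u not in recording.trains]
    if missing:
        raise ValueError(f"units not in recording: {missing}")
    n = len(unit_ids)
    values = np.full((n, n), DIAGONAL_VALUE[method])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    jobs = [
        (recording.trains[unit_ids[i]], recording.trains[unit_ids[j]], method, params)
        for i, j in pairs
    ]
    if n_processes > 1 and jobs:
        with ProcessPoolExecutor(max_workers=n_processes) as pool:
            results = list(pool.map(_pair_value, jobs, chunksize=max(1, len(jobs) // (4 * n_processes))))
    else:
        results = [_pair_value(job) for job in jobs]
    for (i, j), v in zip(pairs, results):
        values[i, j] = values[j, i] = v
    return SynchronyMatrix(method=method, params=params, unit_ids=list(unit_ids), values=values)
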