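"""Seeded generators with known ground truth for every analysis stage.

Each generator draws from its own `numpy` Generator seeded by the single
integer ``seed``, so runs are reproducible and independent of call order.
The defaults emulate the firing statistics typical of mature neuronal
cultures on HD-MEA chips: background firing of a fraction of a hertz to a
few hertz, bursts of ~5-10 spikes at 3-10 ms intra-burst intervals, network
events recruiting most units within tens of milliseconds, biphasic spike
templates of tens of microvolts, and raw traces with broken or noisy
channels.
"""

from __future__ import annotations

import numpy as np

from .core import Recording, SpikeTrain
from .waveform import RawTraces, UnitTemplate

__all__ = [
    "gen_poisson_train",
    "gen_bursty_train",
    "gen_network_recording",
    "gen_jittered_pair",
    "gen_templates",
    "gen_raw_traces",
]


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.array([])
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def gen_poisson_train(
    rate: float, duration: float, seed: int, unit_id: int = 0
) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz."""
    if rate < 0 or duration <= 0:
        raise ValueError("need rate >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    return SpikeTrain(unit_id, _poisson_times(rng, rate, duration), duration)


def gen_bursty_train(
    event_rate: float = 0.1,
    spikes_per_burst: int = 8,
    intra_isi: float = 0.005,
    background_rate: float = 0.0,
    duration: float = 500.0,
    seed: int = 0,
    unit_id: int = 0,
) -> tuple[SpikeTrain, list[tuple[float, float]]]:
    """Bursty train with bimodal ISI structure and true burst intervals.

    Burst events occur at Poisson times; each is a run of
    ``spikes_per_burst`` spikes with intra-burst intervals jittered ±10%
    around ``intra_isi``.  Optional Poisson background spikes are added on
    top.  Returns the train and the ground-truth (start, end) intervals
    (overlapping generated bursts are merged in the ground truth).
    """
    rng = np.random.default_rng(seed)
    span = (spikes_per_burst - 1) * intra_isi * 1.1
    n_events = rng.poisson(event_rate * duration)
    starts = np.sort(rng.uniform(0.0, max(duration - span, 0.0), n_events))
    spikes = []
    truth: list[tuple[float, float]] = []
    for s in starts:
        isis = intra_isi * rng.uniform(0.9, 1.1, spikes_per_burst - 1)
        burst = s + np.concatenate([[0.0], np.cumsum(isis)])
        spikes.append(burst)
        if truth and s <= truth[-1][1]:
            truth[-1] = (truth[-1][0], max(truth[-1][1], burst[-1]))
        else:
            truth.append((s, burst[-1]))
    spikes.append(_poisson_times(rng, background_rate, duration))
    times = np.sort(np.concatenate(spikes)) if spikes else np.array([])
    return SpikeTrain(unit_id, times, duration), truth


def gen_network_recording(
    n_units: int = 20,
    nb_rate: float = 0.05,
    leader: int = 0,
    lag: float = 0.020,
    jitter_sd: float = 0.005,
    participation: float = 1.0,
    duration: float = 600.0,
    seed: int = 0,
    spikes_per_burst: int = 6,
    intra_isi: float = 0.005,
    sampling_rate: float = 20000.0,
) -> tuple[Recording, list[dict]]:
    """Recording with population burst events and a designated leader.

    Population events occur at Poisson times (thinned by a short dead time
    so distinct events stay separable); inside an event each participating
    unit (probability ``participation``) emits a burst whose onset lags the
    event time by its own unit lag plus Gaussian noise (SD ``jitter_sd``).
    Unit lags form a cascade — the leader fires at the event time, the
    remaining units at successive multiples of ``lag`` — so with the
    defaults the leader precedes its nearest follower by 20 ms on average
    and successive onsets inside an event are ~20 ms apart.  Returns the
    recording and the true event list (time, participants, leader, onsets).
    """
    rng = np.random.default_rng(seed)
    burst_span = (spikes_per_burst - 1) * intra_isi
    span = (n_units - 1) * lag + burst_span
    margin = span + 5 * jitter_sd + 0.001
    raw_events = np.sort(
        rng.uniform(margin, duration - margin, rng.poisson(nb_rate * duration))
    )
    # dead time keeps consecutive events from running into each other
    event_times = []
    for et in raw_events:
        if not event_times or et - event_times[-1] >= span + 0.5:
            event_times.append(et)
    rank = {u: i for i, u in enumerate([leader] + [u for u in range(n_units) if u != leader])}
    unit_spikes: dict[int, list[np.ndarray]] = {u: [] for u in range(n_units)}
    truth: list[dict] = []
    for et in event_times:
        participants = [
            u for u in range(n_units) if u == leader or rng.random() <= participation
        ]
        onsets = {}
        for u in participants:
            onset = et + rank[u] * lag + rng.normal(0.0, jitter_sd)
            onset = float(np.clip(onset, 0.0, duration - burst_span))
            isis = intra_isi * rng.uniform(0.9, 1.1, spikes_per_burst - 1)
            unit_spikes[u].append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
            onsets[u] = onset
        truth.append(
            {"time": float(et), "participants": set(participants), "leader": leader,
             "onsets": onsets}
        )
    trains = {
        u: SpikeTrain(
            u,
            np.sort(np.concatenate(chunks)) if chunks else np.array([]),
            duration,
        )
        for u, chunks in unit_spikes.items()
    }
    return Recording(trains, duration, sampling_rate), truth


def gen_jittered_pair(
    rate: float = 2.0,
    jitter_sd: float = 0.0,
    duration: float = 300.0,
    seed: int = 0,
) -> tuple[SpikeTrain, SpikeTrain]:
    """A Poisson train and a Gaussian-jittered copy (re-sorted, clipped)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    times = _poisson_times(rng, rate, duration)
    if jitter_sd > 0:
        jittered = np.sort(
            np.clip(times + rng.normal(0.0, jitter_sd, times.size), 0.0, duration)
        )
    else:
        jittered = times.copy()
    return SpikeTrain(0, times, duration), SpikeTrain(1, jittered, duration)


def gen_templates(
    kind: str = "soma",
    amplitude: float = 80.0,
    noise_sd: float = 0.0,
    n_channels: int = 5,
    sampling_rate: float = 20000.0,
    seed: int = 0,
) -> UnitTemplate:
    """Biphasic spike template with a dominant trough (soma) or peak (dendrite).

    The central channel carries a waveform whose dominant extremum has the
    given ``amplitude`` (µV) and whose opposite phase is 30% of it; the
    amplitude decays geometrically on neighboring channels; white noise of
    SD ``noise_sd`` is added everywhere.  The window is the standard 1 ms
    before to 2 ms after the spike.
    """
    if kind not in ("soma", "dendrite"):
        raise ValueError("kind must be 'soma' or 'dendrite'")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    rng = np.random.default_rng(seed)
    n_samples = round(0.003 * sampling_rate)
    t = np.arange(n_samples) / sampling_rate - 0.001  # s, spike at t = 0
    trough = -np.exp(-0.5 * (t / 0.0002) ** 2)        # 0.2 ms wide
    peak = 0.3 * np.exp(-0.5 * ((t - 0.0007) / 0.0004) ** 2)
    shape = trough + peak
    if kind == "dendrite":
        shape = -shape
    shape = shape / np.max(np.abs(shape)) * amplitude
    central = n_channels // 2
    decay = 0.4 ** np.abs(np.arange(n_channels) - central)
    waveform = decay[:, None] * shape[None, :]
    waveform = waveform + rng.normal(0.0, noise_sd, waveform.shape)
    return UnitTemplate(waveform, sampling_rate)


def gen_raw_traces(
    n_channels: int = 16,
    n_frames: int = 2000,
    sampling_rate: float = 20000.0,
    broken: set[int] | None = None,
    noisy: set[int] | None = None,
    noise_factor: float = 2.0,
    seed: int = 0,
    baseline_sd: float = 5.0,
) -> RawTraces:
    """Raw voltage traces with optional broken and noisy channels.

    Baseline channels are white noise of SD ``baseline_sd`` µV; broken
    channels hold a constant value for a run of at least 10 frames; noisy
    channels have their SD scaled by ``noise_factor``.
    """
    broken = set(broken or ())
    noisy = set(noisy or ())
    if broken & noisy:
        raise ValueError("broken and noisy channel sets must be disjoint")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, baseline_sd, (n_channels, n_frames))
    for ch in noisy:
        values[ch] *= noise_factor
    run = max(10, n_frames // 4)
    for ch in broken:
        start = int(rng.integers(0, max(n_frames - run, 1)))
        values[ch, start : start + run] = values[ch, start]
    return RawTraces(values, sampling_rate)
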