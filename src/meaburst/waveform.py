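"""Raw-trace channel QC, band-pass filtering, and spike-template metrics.

Channels carrying runs of constant samples (saturated or disconnected
electrodes) or with noise far above the array median are flagged before any
spike-level analysis.  Mean spike templates — the average multi-channel
voltage trace from 1 ms before to 2 ms after each spike — are summarized by
their signed height and trough-to-peak duration, and classified as soma-like
(dominant negative deflection) or dendrite-like (dominant positive one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Recording, ValidationError

logger = logging.getLogger("meaburst")

__all__ = [
    "RawTraces",
    "UnitTemplate",
    "detect_bad_channels",
    "bandpass_filter",
    "characterize_template",
    "classify_units",
]


@dataclass
class RawTraces:
    """Multi-channel voltage traces in microvolts (channels x frames)."""

    values: np.ndarray
    sampling_rate: float
    channel_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.shape[0] < 1:
            raise ValidationError("need at least one channel")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.values.shape[0]))
        elif len(self.channel_ids) != self.values.shape[0]:
            raise ValidationError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class UnitTemplate:
    """Mean spike waveform (channels x samples, µV), 1 ms pre to 2 ms post.

    ``central_channel`` is the row with the largest peak-to-peak amplitude.
    """

    waveform: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        expected = round(0.003 * self.sampling_rate)
        if abs(self.waveform.shape[1] - expected) > 1:
            raise ValidationError(
                f"template has {self.waveform.shape[1]} samples; the 3 ms "
                f"window at {self.sampling_rate} Hz requires {expected} ± 1"
            )

    @property
    def central_channel(self) -> int:
        ptp = self.waveform.max(axis=1) - self.waveform.min(axis=1)
        return int(np.argmax(ptp))


def detect_bad_channels(
    traces: RawTraces, sd_factor: float = 1.7, const_len: int = 10
) -> dict[int, str]:
    """Flag channels as ``ok``, ``noisy`` or ``constant``.

    A channel is *constant* if it holds any run of at least ``const_len``
    identical consecutive samples (saturation / broken contact), and *noisy*
    if its standard deviation exceeds ``sd_factor`` times the median SD over
    all channels.  Constant takes precedence.  With a single channel the
    median-based noise test is skipped.
    """
    if const_len < 2:
        raise ValueError("const_len must be >= 2")
    if sd_factor <= 0:
        raise ValueError("sd_factor must be > 0")
    values = traces.values
    sds = values.std(axis=1)
    median_sd = float(np.median(sds)) if traces.n_channels > 1 else None

    flags: dict[int, str] = {}
    for i, cid in enumerate(traces.channel_ids):
        if _longest_constant_run(values[i]) >= const_len:
            flags[cid] = "constant"
        elif median_sd is not None and sds[i] > sd_factor * median_sd:
            flags[cid] = "noisy"
        else:
            flags[cid] = "ok"
    return flags


def _longest_constant_run(x: np.ndarray) -> int:
    """Length of the longest run of consecutive equal samples."""
    if x.size == 0:
        return 0
    change = np.flatnonzero(np.diff(x) != 0)
    run_ends = np.concatenate([change, [x.size - 1]])
    run_starts = np.concatenate([[0], change + 1])
    return int(np.max(run_ends - run_starts + 1))


def bandpass_filter(traces: RawTraces, low: float = 300.0, high: float = 6000.0) -> RawTraces:
    """Zero-phase third-order Butterworth band-pass, applied forward-backward.

    ``high`` is capped at 0.95 x Nyquist (with a log message) when it would
    otherwise be unrealisable at the trace sampling rate.
    """
    nyquist = traces.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if low >= nyquist:
        raise ValueError(f"low cutoff {low} Hz >= Nyquist {nyquist} Hz")
    if high > 0.95 * nyquist:
        logger.info("capping high cutoff %g Hz at 0.95 x Nyquist = %g Hz", high, 0.95 * nyquist)
        high = 0.95 * nyquist
    sos = signal.butter(3, [low, high], btype="bandpass", fs=traces.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, traces.values, axis=1)
    return RawTraces(filtered, traces.sampling_rate, list(traces.channel_ids))


def characterize_template(tpl: UnitTemplate) -> dict:
    """Height, duration and soma/dendrite class of a template.

    On the central channel: a template whose absolute minimum exceeds its
    maximum is soma-like with height = minimum (negative µV); otherwise it is
    dendrite-like with height = maximum (positive µV); ties go to soma-like.
    Duration is the absolute latency between the negative and positive
    extrema in milliseconds.  Returns ``{"undefined": True}`` for an all-zero
    template.
    """
    wave = tpl.waveform[tpl.central_channel]
    if not np.any(wave):
        return {"undefined": True}
    i_min = int(np.argmin(wave))
    i_max = int(np.argmax(wave))
    vmin, vmax = float(wave[i_min]), float(wave[i_max])
    if abs(vmin) >= vmax:
        cls, height = "soma-like", vmin
    else:
        cls, height = "dendrite-like", vmax
    duration_ms = abs(i_max - i_min) / tpl.sampling_rate * 1000.0
    return {"height": height, "duration": duration_ms, "class": cls, "undefined": False}


def classify_units(recording: Recording) -> tuple[dict[int, dict], dict[str, int]]:
    """Characterize every unit with a template; return per-unit results + class counts."""
    results: dict[int, dict] = {}
    counts = {"soma-like": 0, "dendrite-like": 0}
    missing = [uid for uid in recording.unit_ids if uid not in recording.templates]
    if missing:
        logger.info("no template for units %s; excluded from characterization", missing)
    for uid, tpl in sorted(recording.templates.items()):
        res = characterize_template(tpl)
        results[uid] = res
        if not res.get("undefined", False):
            counts[res["class"]] += 1
    return results, counts
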