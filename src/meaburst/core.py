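"""Domain types shared by all analysis stages.

Times are seconds throughout; array positions are micrometres; voltages are
microvolts.  Spike times inside a :class:`SpikeTrain` are kept sorted and
bounded by the recording duration, so downstream detectors never re-validate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("meaburst")

__all__ = [
    "SpikeTrain",
    "Recording",
    "Burst",
    "NetworkBurst",
    "ISIHistogram",
    "SynchronyMatrix",
    "AnalysisResult",
    "SchemaError",
    "ValidationError",
]


class SchemaError(KeyError):
    """A spike archive is missing a required key."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one spike-sorted unit.

    Parameters
    ----------
    unit_id : int
        Integer label assigned by the spike sorter.
    times : ndarray of float
        Spike times in seconds, non-decreasing, within ``[0, duration]``.
    duration : float
        Recording length in seconds (> 0).
    position : tuple of float, optional
        (x, y) location on the array in micrometres.
    """

    unit_id: int
    times: np.ndarray
    duration: float
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if times.ndim != 1:
            raise ValidationError("spike times must be one-dimensional")
        if times.size and np.any(np.diff(times) < 0):
            warnings.warn(
                f"unit {self.unit_id}: spike times were unsorted; sorting",
                stacklevel=2,
            )
            times = np.sort(times)
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValidationError(
                f"unit {self.unit_id}: spike times outside [0, {self.duration}]"
            )
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds (length ``n_spikes - 1``)."""
        return np.diff(self.times)


@dataclass
class Recording:
    """One HD-MEA recording session: spike trains plus shared context."""

    trains: dict[int, SpikeTrain]
    duration: float
    sampling_rate: float
    layout: tuple[int, int] = (64, 64)
    templates: dict[int, "UnitTemplate"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        for uid, train in self.trains.items():
            if train.unit_id != uid:
                raise ValidationError(f"train keyed {uid} has unit_id {train.unit_id}")
            if train.duration != self.duration:
                raise ValidationError(
                    f"unit {uid}: train duration {train.duration} != "
                    f"recording duration {self.duration}"
                )

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.trains)

    def __len__(self) -> int:
        return len(self.trains)


@dataclass(frozen=True)
class Burst:
    """A run of spikes from one unit with short inter-spike intervals.

    ``start`` and ``end`` are the first and last spike time of the run, so the
    interval is closed and ``duration = end - start``.
    """

    unit_id: int
    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("burst end before start")
        if self.n_spikes < 1:
            raise ValidationError("burst must contain at least one spike")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def density(self) -> float:
        """Spikes per second within the burst; NaN for zero duration."""
        if self.duration == 0:
            return float("nan")
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class NetworkBurst:
    """Near-simultaneous bursting of several units.

    ``onsets`` maps every participant to its first burst onset inside the
    event; the leader is the participant with the minimal onset.
    """

    start: float
    end: float
    participants: frozenset[int]
    onsets: Mapping[int, float]
    leader: int
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("network burst end before start")
        if self.leader not in self.participants:
            raise ValidationError("leader must be a participant")
        if set(self.onsets) != set(self.participants):
            raise ValidationError("onsets must cover exactly the participants")
        min_onset = min(self.onsets.values())
        if self.onsets[self.leader] != min_onset:
            raise ValidationError("leader must have the minimal onset")

    @property
    def n_units(self) -> int:
        return len(self.participants)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ISIHistogram:
    """Log10-binned interval histogram used by the adaptive threshold search.

    Bin edges are log10 of the interval in *milliseconds*; the derived
    ``threshold`` (if any) is converted back to seconds.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    voids: dict[tuple[int, int], float] = field(default_factory=dict)
    threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValidationError("counts/edges length mismatch")
        if len(self.smoothed) != len(self.counts):
            raise ValidationError("smoothed/counts length mismatch")
        for v in self.voids.values():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"void value {v} outside [0, 1]")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


#: identity value each synchrony method assigns to the matrix diagonal
DIAGONAL_VALUE = {"sttc": 1.0, "spike_distance": 0.0, "phase_synchrony": 1.0}


@dataclass
class SynchronyMatrix:
    """Pairwise synchrony values for one method and parameter set."""

    method: str
    params: dict
    unit_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in DIAGONAL_VALUE:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of "
                f"{sorted(DIAGONAL_VALUE)}"
            )
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match unit_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("synchrony matrix must be symmetric")

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.unit_ids)


@dataclass
class AnalysisResult:
    """Everything one pipeline run computed, ready for tabular export."""

    recording: Recording
    active_units: set[int]
    unit_stats: dict[int, dict]
    bursts: list[Burst]
    network_bursts: list[NetworkBurst]
    leader_counts: dict[int, dict]
    graph_edges: dict[tuple[int, int], int]
    synchrony: list[SynchronyMatrix]
    settings: dict

    def __post_init__(self) -> None:
        for b in self.bursts:
            if b.unit_id not in self.active_units:
                raise ValidationError(f"burst unit {b.unit_id} not active")
        for nb in self.network_bursts:
            stray = nb.participants - self.active_units
            if stray:
                raise ValidationError(f"network-burst units {stray} not active")
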