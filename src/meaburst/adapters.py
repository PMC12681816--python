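"""Adapters mapping third-party spike-train exports onto the archive schema.

Spike-sorting pipelines export per-unit spike trains under varying key
conventions.  :func:`load_unit_npz` ingests a keyed NumPy archive that
stores one spike-time array per unit, recognizing several common layouts;
archives already in the native schema go through
:func:`meaburst.io.load_spike_archive` directly.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import Recording, SchemaError, SpikeTrain

__all__ = ["load_unit_npz"]

# common per-unit key conventions: "unit_7", "spike_times_7", "7", "times_7"
_UNIT_KEY = re.compile(r"^(?:unit_|spike_times_|times_)?(\d+)$")


def load_unit_npz(
    path: str | Path,
    duration: float | None = None,
    sampling_rate: float = 20000.0,
    in_frames: bool = False,
) -> Recording:
    """Build a :class:`Recording` from an npz of per-unit spike-time arrays.

    Keys matching ``unit_<id>``, ``spike_times_<id>``, ``times_<id>`` or a
    bare integer are treated as one unit each.  ``duration`` and
    ``sampling_rate`` are taken from same-named keys when present and must
    otherwise be supplied; with ``in_frames`` spike times are frame indices
    and are divided by the sampling rate on ingest.
    """
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        data = {k: npz[k] for k in npz.files}
    if "duration" in data:
        duration = float(np.asarray(data.pop("duration")).item())
    if "sampling_rate" in data:
        sampling_rate = float(np.asarray(data.pop("sampling_rate")).item())
    units: dict[int, np.ndarray] = {}
    for key, value in data.items():
        match = _UNIT_KEY.match(key)
        if match and np.asarray(value).ndim == 1:
            units[int(match.group(1))] = np.asarray(value, dtype=float)
    if not units:
        raise SchemaError(
            f"{path.name}: no per-unit spike-time keys recognized "
            "(expected e.g. 'unit_<id>' or 'spike_times_<id>')"
        )
    if in_frames:
        units = {uid: t / sampling_rate for uid, t in units.items()}
    if duration is None:
        last = max(t[-1] for t in units.values() if t.size)
        duration = float(np.ceil(last))
    trains = {uid: SpikeTrain(uid, times, duration) for uid, times in units.items()}
    return Recording(trains, duration, sampling_rate)
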