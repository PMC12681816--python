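"""Spike-archive reading/writing and tabular export.

The spike archive is a self-describing keyed-array container available in
two dialects with identical key names: a zipped NumPy archive (``.npz``)
and HDF5 (``.h5``/``.hdf5``).  Keys:

``unit_ids``
    integer array of unit labels
``spike_times_<id>``
    float spike times of each unit, seconds
``duration``, ``sampling_rate``
    scalars, seconds and Hz
``positions`` (optional)
    N x 2 array of (x, y) µm, aligned with ``unit_ids``
``template_<id>`` + ``template_fs`` (optional)
    channels x samples mean waveform in µV and its sampling rate
``raw_traces`` (optional, HDF5)
    channels x frames voltage traces in µV

Analysis results export to ODS / XLSX workbooks or a directory of CSV
files with one sheet/file per table (units, bursts, network_bursts, one
synchrony sheet per method, settings).
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import AnalysisResult, Recording, SchemaError, SpikeTrain
from .waveform import UnitTemplate

__all__ = ["load_spike_archive", "save_spike_archive", "export_tables"]

_REQUIRED_KEYS = ("unit_ids", "duration", "sampling_rate")


def _recording_from_mapping(data: dict) -> Recording:
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise SchemaError(f"archive is missing required key {key!r}")
    duration = float(np.asarray(data["duration"]).item())
    sampling_rate = float(np.asarray(data["sampling_rate"]).item())
    unit_ids = np.asarray(data["unit_ids"], dtype=int).ravel()
    positions = data.get("positions")
    if positions is not None:
        positions = np.asarray(positions, dtype=float).reshape(len(unit_ids), 2)
    template_fs = data.get("template_fs")

    trains: dict[int, SpikeTrain] = {}
    templates: dict[int, UnitTemplate] = {}
    for i, uid in enumerate(unit_ids):
        uid = int(uid)
        key = f"spike_times_{uid}"
        if key not in data:
            raise SchemaError(f"archive is missing required key {key!r}")
        pos = tuple(positions[i]) if positions is not None else None
        trains[uid] = SpikeTrain(uid, np.asarray(data[key], dtype=float), duration, pos)
        tkey = f"template_{uid}"
        if tkey in data:
            if template_fs is None:
                raise SchemaError("archive has templates but no 'template_fs' key")
            templates[uid] = UnitTemplate(
                np.asarray(data[tkey], dtype=float),
                float(np.asarray(template_fs).item()),
            )
    layout = data.get("layout")
    layout = tuple(np.asarray(layout, dtype=int)) if layout is not None else (64, 64)
    return Recording(trains, duration, sampling_rate, layout, templates)


def load_spike_archive(path: str | os.PathLike) -> Recording:
    """Read a spike archive (``.npz`` or HDF5) into a :class:`Recording`.

    Unsorted spike times are sorted with a warning; times outside
    ``[0, duration]`` or a non-positive duration raise a validation error;
    a missing required key raises :class:`SchemaError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            return _recording_from_mapping({k: npz[k] for k in npz.files})
    with h5py.File(path, "r") as fh:
        return _recording_from_mapping({k: fh[k][()] for k in fh.keys()})


def _recording_to_mapping(recording: Recording) -> dict:
    unit_ids = recording.unit_ids
    data: dict = {
        "unit_ids": np.asarray(unit_ids, dtype=int),
        "duration": np.float64(recording.duration),
        "sampling_rate": np.float64(recording.sampling_rate),
        "layout": np.asarray(recording.layout, dtype=int),
    }
    if unit_ids and all(recording.trains[u].position is not None for u in unit_ids):
        data["positions"] = np.array(
            [recording.trains[u].position for u in unit_ids], dtype=float
        )
    for uid in unit_ids:
        data[f"spike_times_{uid}"] = recording.trains[uid].times
    if recording.templates:
        fs = {t.sampling_rate for t in recording.templates.values()}
        if len(fs) != 1:
            raise ValueError("all templates must share one sampling rate")
        data["template_fs"] = np.float64(fs.pop())
        for uid, tpl in recording.templates.items():
            data[f"template_{uid}"] = tpl.waveform
    return data


def save_spike_archive(recording: Recording, path: str | os.PathLike) -> Path:
    """Write a :class:`Recording` so that :func:`load_spike_archive` restores it."""
    path = Path(path)
    data = _recording_to_mapping(recording)
    if path.suffix == ".npz":
        np.savez(path, **data)
    else:
        with h5py.File(path, "w") as fh:
            for key, value in data.items():
                fh[key] = value
    return path


def _units_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    n_bursts = {}
    for b in result.bursts:
        n_bursts[b.unit_id] = n_bursts.get(b.unit_id, 0) + 1
    for uid in sorted(result.active_units):
        stats = result.unit_stats.get(uid, {})
        train = result.recording.trains.get(uid)
        pos = train.position if train is not None else None
        leaders = result.leader_counts.get(uid, {})
        rows.append(
            {
                "unit_id": uid,
                "x": pos[0] if pos else np.nan,
                "y": pos[1] if pos else np.nan,
                "firing_rate": stats.get("firing_rate", np.nan),
                "isi_violation_ratio": stats.get("isi_violation_ratio", np.nan),
                "template_height": stats.get("template_height", np.nan),
                "template_duration": stats.get("template_duration", np.nan),
                "template_class": stats.get("template_class", ""),
                "n_bursts": n_bursts.get(uid, 0),
                "n_led": leaders.get("n_led", 0),
                "n_participated": leaders.get("n_participated", 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "x", "y", "firing_rate", "isi_violation_ratio",
            "template_height", "template_duration", "template_class",
            "n_bursts", "n_led", "n_participated",
        ],
    )


def _bursts_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = [
        {
            "unit_id": b.unit_id,
            "start": b.start,
            "end": b.end,
            "n_spikes": b.n_spikes,
            "duration": b.duration,
            "density": b.density,
        }
        for b in result.bursts
    ]
    return pd.DataFrame(
        rows, columns=["unit_id", "start", "end", "n_spikes", "duration", "density"]
    )


def _network_bursts_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = [
        {
            "start": nb.start,
            "end": nb.end,
            "n_units": nb.n_units,
            "leader": nb.leader,
            "n_spikes": nb.n_spikes,
        }
        for nb in result.network_bursts
    ]
    return pd.DataFrame(rows, columns=["start", "end", "n_units", "leader", "n_spikes"])


def _settings_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = [{"parameter": k, "value": str(v)} for k, v in sorted(result.settings.items())]
    return pd.DataFrame(rows, columns=["parameter", "value"])


def _all_frames(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    frames = {
        "units": _units_frame(result),
        "bursts": _bursts_frame(result),
        "network_bursts": _network_bursts_frame(result),
    }
    for mat in result.synchrony:
        frame = mat.as_frame()
        frame.insert(0, "unit_id", mat.unit_ids)
        frames[f"synchrony_{mat.method}"] = frame
    frames["settings"] = _settings_frame(result)
    return frames


def export_tables(
    result: AnalysisResult, path: str | os.PathLike, format: str = "xlsx"
) -> Path:
    """Export an analysis result to ``ods``, ``xlsx`` or a ``csv-dir``.

    For workbook formats ``path`` is the file; for ``csv-dir`` it is a
    directory that receives one UTF-8 CSV per sheet.  Exported numbers are
    written at full precision so re-reading reproduces them exactly.
    """
    path = Path(path)
    frames = _all_frames(result)
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(path / f"{name}.csv", index=False)
        return path
    if format not in ("ods", "xlsx"):
        raise ValueError(
            f"unknown format {format!r}; supported formats: ods, xlsx, csv-dir"
        )
    if format == "ods":
        try:
            import odf  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "ODS export requires the optional 'odfpy' dependency "
                "(pip install meaburst[ods]); xlsx and csv-dir need no extras"
            ) from exc
    engine = "odf" if format == "ods" else "openpyxl"
    if path.suffix != f".{format}":
        path = path.with_suffix(f".{format}")
    with pd.ExcelWriter(path, engine=engine) as writer:
        for name, frame in frames.items():
            frame.to_excel(writer, sheet_name=name[:31], index=False)
    return path
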