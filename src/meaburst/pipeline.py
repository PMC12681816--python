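"""End-to-end analysis of one or more spike archives.

Per recording: active-unit selection -> optional ISI-violation filter ->
burst detection -> network bursts (+ optional merging) -> leaders and
precedence graph -> synchrony matrices -> template classification -> table,
edge-list and plot export, with a per-recording log.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import bursts as _bursts
from . import network as _network
from .config import flatten, load_config
from .core import AnalysisResult, Recording
from .io import export_tables, load_spike_archive
from .synchrony import pairwise_matrix
from .units import (
    filter_by_isi_violations,
    firing_rate,
    isi_violation_ratio,
    select_active_units,
)
from .waveform import characterize_template

logger = logging.getLogger("meaburst")

__all__ = ["analyze_recording", "run_pipeline", "NoActiveUnitsError"]


class NoActiveUnitsError(RuntimeError):
    """No unit passed the activity filters."""


def _burst_params(cfg: dict) -> _bursts.BurstParams:
    return _bursts.BurstParams(
        max_isi=cfg["max_isi"],
        min_spikes=cfg["min_spikes"],
        max_isi_threshold=cfg["max_isi_threshold"],
        isi_choice=cfg["isi_choice"],
        max_intra_peak=cfg["max_intra_peak"],
        bin_size=cfg["bin_size"],
        smooth_window=cfg["smooth_window"],
        smooth_order=cfg["smooth_order"],
        peak_min_distance=cfg["peak_min_distance"],
        min_void=cfg["min_void"],
    )


def _nb_params(cfg: dict) -> _network.NetworkBurstParams:
    return _network.NetworkBurstParams(
        max_ibei=cfg["max_ibei"],
        min_units=cfg["min_units"],
        min_separation=cfg["min_separation"],
        max_intra_peak=cfg["max_intra_peak"],
        bin_size=cfg["bin_size"],
        smooth_window=cfg["smooth_window"],
        smooth_order=cfg["smooth_order"],
        peak_min_distance=cfg["peak_min_distance"],
        min_void=cfg["min_void"],
    )


def analyze_recording(recording: Recording, config: dict | None = None) -> AnalysisResult:
    """Run the full analysis on one recording, returning an :class:`AnalysisResult`."""
    config = config or load_config()
    spikes_cfg = config["spikes"]

    active = select_active_units(recording, spikes_cfg["min_firing_rate"])
    if spikes_cfg["max_isi_violation_ratio"] > 0:
        active &= filter_by_isi_violations(
            recording,
            spikes_cfg["max_isi_violation_ratio"],
            spikes_cfg["isi_violation_threshold"],
        )
    if not active:
        raise NoActiveUnitsError("no unit passed the activity filters")
    logger.info("%d of %d units active", len(active), len(recording))

    unit_stats: dict[int, dict] = {}
    for uid in sorted(active):
        train = recording.trains[uid]
        stats = {
            "firing_rate": firing_rate(train),
            "n_spikes": train.n_spikes,
            "isi_violation_ratio": isi_violation_ratio(
                train, spikes_cfg["isi_violation_threshold"]
            ),
        }
        if uid in recording.templates:
            char = characterize_template(recording.templates[uid])
            if not char.get("undefined", False):
                stats["template_height"] = char["height"]
                stats["template_duration"] = char["duration"]
                stats["template_class"] = char["class"]
        unit_stats[uid] = stats

    burst_cfg = config["bursts"]
    method = burst_cfg["method"]
    bursts_by_unit: dict[int, list] = {}
    for uid in sorted(active):
        train = recording.trains[uid]
        if method == "fixed":
            found = _bursts.detect_bursts_fixed(
                train, burst_cfg["max_isi"], burst_cfg["min_spikes"]
            )
        elif method == "adaptive":
            found, _ = _bursts.detect_bursts_adaptive(train, _burst_params(burst_cfg))
        elif method == "hybrid":
            found = _bursts.detect_bursts_hybrid(train, _burst_params(burst_cfg))
        else:
            raise ValueError(f"unknown burst method {method!r}")
        bursts_by_unit[uid] = found
    all_bursts = sorted(
        (b for bs in bursts_by_unit.values() for b in bs),
        key=lambda b: (b.start, b.unit_id),
    )

    nb_cfg = config["network_bursts"]
    if nb_cfg["method"] == "fixed":
        nbs = _network.detect_network_bursts_fixed(
            bursts_by_unit, nb_cfg["max_ibei"], nb_cfg["min_units"]
        )
    elif nb_cfg["method"] == "adaptive":
        nbs, _ = _network.detect_network_bursts_adaptive(bursts_by_unit, _nb_params(nb_cfg))
    else:
        raise ValueError(f"unknown network-burst method {nb_cfg['method']!r}")
    nbs = _network.merge_network_bursts(nbs, nb_cfg["min_separation"])
    leader_counts = _network.identify_leaders(nbs)
    edges = _network.network_graph(nbs)
    logger.info("%d bursts, %d network bursts", len(all_bursts), len(nbs))

    sync_cfg = config["synchrony"]
    method_params = {
        "sttc": {"dt": sync_cfg["sttc_dt"]},
        "spike_distance": {"n_bin": sync_cfg["spike_distance_bins"]},
        "phase_synchrony": {},
    }
    matrices = [
        pairwise_matrix(
            recording,
            sorted(active),
            m,
            method_params[m],
            config["general"]["n_processes"],
        )
        for m in sync_cfg["methods"]
    ]

    return AnalysisResult(
        recording=recording,
        active_units=active,
        unit_stats=unit_stats,
        bursts=all_bursts,
        network_bursts=nbs,
        leader_counts=leader_counts,
        graph_edges=edges,
        synchrony=matrices,
        settings=flatten(config),
    )


def _summary_plots(result: AnalysisResult, out_dir: Path, plot_cfg: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fmt = plot_cfg["format"]
    unit_ids = sorted(result.active_units)

    fig, ax = plt.subplots(figsize=(10, 6))
    for row, uid in enumerate(unit_ids):
        t = result.recording.trains[uid].times
        ax.vlines(t, row + 0.6, row + 1.4, lw=0.4, color="k")
    for nb in result.network_bursts:
        ax.axvspan(nb.start, nb.end, color="tab:orange", alpha=0.3, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("unit")
    ax.set_title("raster (network bursts shaded)")
    fig.savefig(out_dir / f"raster.{fmt}")
    plt.close(fig)

    for mat in result.synchrony:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.values, cmap=plot_cfg["colormap"])
        fig.colorbar(im, ax=ax, label=mat.method)
        ax.set_title(f"{mat.method} ({len(mat.unit_ids)} units)")
        fig.savefig(out_dir / f"synchrony_{mat.method}.{fmt}")
        plt.close(fig)

    if any(result.recording.trains[u].position is not None for u in unit_ids):
        fig, ax = plt.subplots(figsize=(6, 5))
        xs, ys, rates = [], [], []
        for uid in unit_ids:
            pos = result.recording.trains[uid].position
            if pos is not None:
                xs.append(pos[0])
                ys.append(pos[1])
                rates.append(result.unit_stats[uid]["firing_rate"])
        sc = ax.scatter(xs, ys, c=rates, cmap=plot_cfg["colormap"])
        fig.colorbar(sc, ax=ax, label="firing rate (Hz)")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        fig.savefig(out_dir / f"rate_map.{fmt}")
        plt.close(fig)


def run_pipeline(
    inputs: list[str | Path],
    config_path: str | Path | None = None,
    out_dir: str | Path = "output",
    export_format: str | None = None,
    make_plots: bool = True,
) -> dict[str, int]:
    """Analyze each archive and export tables, edge list, plots and a log.

    Returns a per-input exit status (0 success, 1 failure); inputs that
    fail — e.g. a recording with no active unit — are logged and skipped
    without aborting the batch.
    """
    config = load_config(config_path)
    if export_format is None:
        export_format = config["general"]["export_format"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    statuses: dict[str, int] = {}
    for input_path in inputs:
        input_path = Path(input_path)
        rec_dir = out_dir / input_path.stem
        rec_dir.mkdir(parents=True, exist_ok=True)
        log_path = rec_dir / "analysis.log"
        handler = logging.FileHandler(log_path, mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        try:
            logger.info("settings: %s", flatten(config))
            recording = load_spike_archive(input_path)
            result = analyze_recording(recording, config)
            if export_format == "csv-dir":
                export_tables(result, rec_dir / "tables", "csv-dir")
            else:
                export_tables(result, rec_dir / f"tables.{export_format}", export_format)
            _network.write_edge_list(result.graph_edges, rec_dir / "network_edges.tsv")
            if make_plots:
                _summary_plots(result, rec_dir, config["plotting"])
            statuses[str(input_path)] = 0
        except Exception as exc:  # per-file isolation: one bad input never kills the batch
            logger.error("failed: %s", exc)
            statuses[str(input_path)] = 1
        finally:
            logger.removeHandler(handler)
            handler.close()
    return statuses
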