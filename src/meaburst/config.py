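"""Pipeline settings: defaults and TOML loading.

Settings are grouped into sections mirroring the analysis stages.  A TOML
settings file may override any subset; unknown sections or keys are
rejected with an error naming the offender, so typos never silently fall
back to defaults.
"""

from __future__ import annotations

import tomllib
from copy import deepcopy
from pathlib import Path

__all__ = ["DEFAULTS", "load_config", "validate_config"]

#: Default analysis settings.  Units: seconds unless stated otherwise.
DEFAULTS: dict[str, dict] = {
    "general": {
        "n_processes": 1,
        "export_format": "ods",
        "analysis_folder": "output",
    },
    "spikes": {
        "min_firing_rate": 0.05,           # Hz
        "max_isi_violation_ratio": 0.0,    # 0 disables the filter
        "isi_violation_threshold": 0.0015,
        "common_active_mode": "all",
        "highpass": 300.0,                 # Hz
        "lowpass": 6000.0,                 # Hz
        "bad_channels_noise_threshold": 1.7,
        "bad_channels_constant_threshold": 10,  # frames
    },
    "synchrony": {
        "methods": ["sttc", "spike_distance", "phase_synchrony"],
        "sttc_dt": 0.5,
        "spike_distance_bins": 120,
    },
    "bursts": {
        "method": "adaptive",              # fixed | adaptive | hybrid
        "min_spikes": 5,
        "max_isi": 0.1,
        "max_isi_threshold": 1.0,
        "isi_choice": 0.1,
        "max_intra_peak": 0.1,
        "bin_size": 0.1,                   # log10 decades
        "smooth_window": 3,                # bins
        "smooth_order": 1,
        "peak_min_distance": 2,            # bins
        "min_void": 0.7,
    },
    "network_bursts": {
        "method": "adaptive",              # fixed | adaptive
        "min_units": 5,
        "max_ibei": 0.2,
        "min_separation": -0.01,           # negative disables merging
        "max_intra_peak": 0.2,
        "bin_size": 0.1,
        "smooth_window": 3,
        "smooth_order": 1,
        "peak_min_distance": 2,
        "min_void": 0.5,
    },
    "plotting": {
        "format": "pdf",
        "colormap": "viridis",
        "afr_bin": 5.0,                    # s
        "abr_bin": 10.0,
        "anbr_bin": 20.0,
    },
}


def validate_config(overrides: dict) -> None:
    """Reject unknown sections or keys, naming the first offender."""
    for section, values in overrides.items():
        if section not in DEFAULTS:
            raise KeyError(
                f"unknown settings section {section!r}; expected one of "
                f"{sorted(DEFAULTS)}"
            )
        if not isinstance(values, dict):
            raise KeyError(f"settings section {section!r} must be a table")
        for key in values:
            if key not in DEFAULTS[section]:
                raise KeyError(
                    f"unknown settings key {section}.{key}; expected one of "
                    f"{sorted(DEFAULTS[section])}"
                )


def load_config(path: str | Path | None = None) -> dict[str, dict]:
    """Defaults, deep-merged with an optional TOML settings file."""
    config = deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            overrides = tomllib.load(fh)
        validate_config(overrides)
        for section, values in overrides.items():
            config[section].update(values)
    return config


def flatten(config: dict[str, dict]) -> dict[str, object]:
    """Flatten to ``section.key`` form for the settings snapshot."""
    return {
        f"{section}.{key}": value
        for section, values in config.items()
        for key, value in values.items()
    }
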