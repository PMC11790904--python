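"""Run configuration: YAML loading with defaults, validation and lossless
round-tripping."""

from __future__ import annotations

import copy
from dataclasses import dataclass

import yaml

from ..errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "results",
    "log_level": "INFO",
    "sicm": {
        "applied_pressure_kpa": 10.0,
        "geometry_factor": 0.4,
        "substrate_slope_per_nm": 1.0e-3,
        "setpoint_fraction": 0.98,
        "slope_window": [0.985, 0.99],
        "noise_sd": 0.0,
        "n_dense": 2001,
        "phantom": {
            "nx": 32,
            "ny": 32,
            "extent_um": 10.0,
            "process_length_um": 5.0,
            "soma_axes_um": [4.0, 3.0],
            "e_soma_kpa": 2.0,
            "e_process_kpa": 3.0,
        },
    },
    "flim": {
        "t_max_ns": 40.0,
        "n_bins": 512,
        "n_photons": 100000,
        "per_pixel": False,
    },
    "ca": {
        "threshold": 0.40,
        "min_separation_s": 10.0,
        "frame_interval_s": 5.0,
    },
    "migration": {
        "eps_um": 0.2,
        "frame_interval_min": 2.0,
    },
    "stretch": {
        "strain": 0.20,
        "onset_min": 15.0,
        "n_cells": 12,
        "duration_min": 30.0,
    },
    "cohort": {
        "n_cells": 50,
        "mean_length_um": 39.0,
        "excursion_um": 11.3,
        "cell_sd_um": 6.0,
        "relaxation_min": 8.0,
        "growth_push_um": 9.5,
        "tension_base_ns": 5.4,
        "tension_gain_ns_per_um": 0.02,
        "tension_noise_ns": 0.05,
        "rate_base_per_min": 0.15,
        "rate_gain_per_min": 1.2,
        "gate_offset_um": 4.0,
        "gate_width_um": 2.0,
        "knockdown": 1.0,
        "duration_min": 120.0,
    },
    "pipeline": {
        "kd_knockdown": 0.2,
        "n_tension_cells": 129,
    },
}


@dataclass
class RunConfig:
    """Validated configuration tree (defaults merged in)."""

    data: dict

    def get(self, dotted: str):
        node = self.data
        for part in dotted.split("."):
            node = node[part]
        return node

    def __eq__(self, other) -> bool:  # structural equality
        return isinstance(other, RunConfig) and self.data == other.data


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"expected mapping at {here}")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path) -> RunConfig:
    """Load a YAML config; an empty (or absent content) file yields pure
    defaults, unknown keys raise :class:`ConfigError` naming the key."""
    with open(path) as f:
        user = yaml.safe_load(f)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig(_merge(DEFAULTS, user))


def default_config() -> RunConfig:
    return RunConfig(copy.deepcopy(DEFAULTS))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.data, f, sort_keys=True)


def cohort_params_from_config(config: RunConfig, **overrides):
    """Build :class:`~neuromech.cohort_sim.CohortParams` from the cohort
    block (plus per-call overrides)."""
    from ..cohort_sim import CohortParams

    kwargs = dict(config.data["cohort"])
    kwargs.setdefault("seed", config.data["seed"])
    kwargs.update(overrides)
    return CohortParams(**kwargs)
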