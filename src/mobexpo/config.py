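"""YAML run configuration: defaults for every stage, strict key validation."""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "io": {"crs_mode": "planar"},
    "preprocess": {"window_s": 300.0, "max_jump_m": 2000.0},
    "resample": {"snap_tol_s": 900.0},
    "anchors": {"alpha_m": 500.0, "beta": 0.2},
    "clustering": {"linkage": "average", "n_clusters": 4},
    "reconstruction": {
        "intervals_s": [3600.0, 7200.0, 10800.0],
        "n_estimators": 200,
        "max_depth": 3,
        "learning_rate": 0.1,
        "subsample": 1.0,
        "min_train_examples": 10,
    },
    "field": {
        "kernel": "bisquare",
        "bandwidth": "select",
        "adaptive": True,
        "variogram_model": "exponential",
        "nugget": 0.0,
        "radius_m": 1000.0,
        "allow_missing": False,
    },
    "grid": {"x0": 0.0, "y0": 0.0, "n_rows": 40, "n_cols": 40, "cell_m": 1000.0},
    "exposure": {"top_frac": 0.2, "night_start": 22, "night_end": 6},
    "calendar": {"weekend_days": [6, 7]},
    "synth": {
        "n_agents": 200,
        "n_clusters": 4,
        "days": 2,
        "sigma": 5.0,
        "n_pm_stations": 60,
        "n_met_stations": 169,
        "jitter_m": 800.0,
        "cdr_share": 0.34,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and explicit overrides; unknown keys rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def write_resolved(cfg: dict, outdir) -> str:
    """Persist the resolved configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "config.resolved.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return str(path)


def day_types_from_config(cfg: dict, days: int) -> dict[int, str]:
    weekend = set(cfg["calendar"]["weekend_days"])
    return {d: ("weekend" if d in weekend else "workday") for d in range(1, days + 1)}
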