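"""TOML application configuration: load, validate, and round-trip.

Sections mirror the module configurations (simulate / encoder / train / rl /
infer / likelihood) plus a global seed and log level.  Unknown sections or
keys are rejected so typos fail loudly.  Reading uses the stdlib ``tomllib``;
a minimal emitter handles writing (scalars and flat sections only, which is
all the app config needs).
"""

from __future__ import annotations

import tomllib
from pathlib import Path

__all__ = ["DEFAULTS", "load_config", "dumps_toml", "merged"]

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "n_taxa": 50,
        "seq_length": 512,
        "count": 10,
        "model": "gtr",
        "deletion_grid": [0.0, 0.01, 0.02, 0.03],
    },
    "encoder": {
        "d_model": 64,
        "n_layers": 2,
        "n_heads": 4,
        "hidden_mult": 4,
        "max_len": 1024,
    },
    "train": {
        "margin": 1.0,
        "lr": 1e-3,
        "batch_size": 8,
        "negatives_per_positive": 4,
        "max_epochs": 10,
        "val_interval": 50,
        "patience": 5,
    },
    "rl": {
        "n_trajectories": 8,
        "epochs": 20,
        "gamma": 1.0,
        "lr": 1e-4,
        "branch_length_mode": "fixed",
    },
    "infer": {
        "mode": "greedy",
        "gamma": 1.0,
        "n_samples": 32,
    },
    "likelihood": {
        "branch_length_mode": "fixed",
    },
}


def load_config(path: str | Path | None) -> dict:
    """Load a TOML config merged over the defaults; reject unknown keys."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config section or key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a table")
            for sub, subval in val.items():
                if sub not in cfg[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")
                cfg[key][sub] = subval
        else:
            cfg[key] = val
    return cfg


def merged(cfg: dict, section: str, **overrides) -> dict:
    """Section values with non-None overrides (CLI flags beat config)."""
    out = dict(cfg[section])
    for k, v in overrides.items():
        if v is not None:
            out[k] = v
    return out


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value)} to TOML")


def dumps_toml(cfg: dict) -> str:
    lines = []
    for key, val in cfg.items():
        if not isinstance(val, dict):
            lines.append(f"{key} = {_fmt(val)}")
    for key, val in cfg.items():
        if isinstance(val, dict):
            lines.append(f"\n[{key}]")
            for sub, subval in val.items():
                lines.append(f"{sub} = {_fmt(subval)}")
    return "\n".join(lines) + "\n"
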