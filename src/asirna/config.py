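"""Structured configuration with per-module sections; CLI flags override the file."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_config"]

DEFAULTS: dict = {
    "sequence": {
        # classify G:U wobble as a mismatch in guide:target clash typing
        "wobble_is_mismatch": True,
    },
    "features": {
        "feature_spec": ["m", "d", "t", "tt", "binary"],
    },
    "model": {
        "hyperparams": {"C": 10.0, "gamma": "scale", "epsilon": 2.0},
        "tune": False,
        "cv_folds": 10,
        "lotocv_min_group": 10,
        "seed": 0,
    },
    "matrix": {
        # multiplicative: Eff_wild = Eff_mut * retention; absolute: Eff_wild = 100 * retention
        "mode": "multiplicative",
        "path": None,
    },
    "offtarget": {
        "seed_mode": "seed6",
        "max_mismatch": 3,
        "both_strands": False,
    },
    "synthetic": {
        "seed": 0,
        "noise_sd": 5.0,
        "effect_model": "linear_dinuc",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file (unknown sections rejected)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return _merge(DEFAULTS, user)


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)
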