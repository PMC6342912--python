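"""Run-configuration files (YAML/JSON) and run manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .dynamics import DynamicsConfig
from .lattice import GameParams
from .memory import MemoryConfig

__all__ = ["load_config", "resolve_config", "save_manifest"]

_DEFAULTS = {
    "T": 1.0,
    "S": 0.0,
    "K": 0.1,
    "L": 100,
    "variant": "none",
    "alpha": 0.0,
    "tau": 0,
    "init": "random",
    "radius": None,
    "relax": 10_000,
    "measure": 20_000,
    "seed": 0,
    "stop_at_absorption": True,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML (or JSON — valid YAML) run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return data


def resolve_config(overrides: dict | None = None, config_path: str | Path | None = None):
    """Merge defaults, a config file, and CLI overrides into typed configs.

    Precedence: explicit overrides > config file > defaults.  Returns
    ``(GameParams, MemoryConfig, DynamicsConfig, init_spec_dict)``.
    """
    merged = dict(_DEFAULTS)
    if config_path is not None:
        merged.update(load_config(config_path))
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    params = GameParams(float(merged["T"]), float(merged["S"]))
    mem = MemoryConfig(
        variant=merged["variant"], alpha=float(merged["alpha"]), tau=int(merged["tau"])
    )
    dyn = DynamicsConfig(
        K=float(merged["K"]),
        relaxation_steps=int(merged["relax"]),
        measure_steps=int(merged["measure"]),
        seed=int(merged["seed"]),
        stop_at_absorption=bool(merged["stop_at_absorption"]),
    )
    init_spec = {
        "init": merged["init"],
        "L": int(merged["L"]),
        "radius": merged["radius"],
        "seed": int(merged["seed"]),
    }
    return params, mem, dyn, init_spec


def save_manifest(path: str | Path, params, mem, dyn, init_spec: dict, extra: dict | None = None):
    """Write the fully resolved configuration of a run as JSON."""
    manifest = {
        "game": {"T": params.T, "S": params.S, "R": params.R, "P": params.P},
        "memory": mem.to_dict(),
        "dynamics": asdict(dyn),
        "init": init_spec,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
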