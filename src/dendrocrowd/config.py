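"""Structured configuration files (YAML/JSON) and run manifests.

A config file has sections ``geometry``, ``calibration``, ``solver``,
``simulation``, ``calcium`` — all optional, all defaults overridable.
Every CLI run writes a reproducibility manifest (resolved configuration,
seed, package version) next to its outputs; re-running from the manifest
reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .reduced.geometry import (
    DEFAULT_CALIBRATION_RATIO,
    CompartmentSpec,
    calibrate_geometry,
)

DEFAULTS = {
    "geometry": {
        "dendrite_radius": 0.5,  # μm
        "total_length": 20.0,  # μm
        "free_diffusion": 400.0,  # μm²/s
    },
    "calibration": {
        "target_ratio": 0.05,  # D_eff / D
        "calibration_ratio": DEFAULT_CALIBRATION_RATIO,  # ε / L
    },
    "solver": {
        "dx": 0.05,  # μm
        "bc": "reflecting",
    },
    "simulation": {
        "n_particles": 10_000,
        "base_step": 1e-5,  # s
        "adaptive_min_fraction": 0.4,
        "sampling_period": 0.7e-3,  # s
        "rng_seed": 0,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults ← file ← overrides (two-level deep merge)."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for section, values in layer.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    return cfg


def compartment_spec_from_config(cfg: dict) -> CompartmentSpec:
    geo, cal = cfg["geometry"], cfg["calibration"]
    return calibrate_geometry(
        cal["target_ratio"],
        geo["dendrite_radius"],
        calibration_ratio=cal["calibration_ratio"],
        D=geo["free_diffusion"],
    )


def write_manifest(out_dir, command: str, cfg: dict, seed: int | None = None,
                   extra: dict | None = None) -> Path:
    """Write the reproducibility manifest for one CLI run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "dendrocrowd",
        "version": __version__,
        "command": command,
        "resolved_config": _plain(cfg),
        "rng_seed": seed,
        "python": platform.python_version(),
    }
    if extra:
        manifest.update(_plain(extra))
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_plain)
    return path


def _plain(obj):
    """Recursively convert dataclasses/arrays to JSON-safe structures."""
    import numpy as np

    if hasattr(obj, "__dataclass_fields__"):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
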