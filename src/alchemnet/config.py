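"""Run configuration: YAML file + flag overrides, unknown keys rejected."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["DEFAULTS", "load_config", "dump_effective_config"]

DEFAULTS: dict = {
    # structure I/O
    "pocket_cutoff_angstrom": 5.0,
    "exclude_waters": True,
    # graph construction
    "noncovalent_cutoff_angstrom": 4.5,
    # model
    "d_hidden": 128,
    "n_layers": 3,
    "d_lambda_basis": 16,
    "activation": "silu",
    "pooling": "sum",
    # training
    "learning_rate": 3e-3,
    "weight_decay": 5e-3,
    "warmup_steps": 100,
    "plateau_patience": 20,
    "plateau_factor": 0.5,
    "early_stop_patience": 80,
    "batch_size": 64,
    "epsilon_kcal": 0.1,
    "use_reliability_weights": True,
    "max_epochs": 250,
    "val_fraction": 0.15,
    # free-energy assembly
    "leg_signs": [1, -1],
    "windows_per_leg": 11,
    # λ schedule optimization
    "threshold_kcal": 10.0,
    "resolution": 0.001,
    "gap_mode": "interval",
    # reproducibility
    "seed": 0,
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge DEFAULTS ← YAML file ← overrides; unknown keys are an error."""
    cfg = dict(DEFAULTS)
    for source, name in ((yaml.safe_load(Path(path).read_text()) if path else None, path),
                         (overrides, "flag overrides")):
        if not source:
            continue
        if not isinstance(source, dict):
            raise ConfigError(f"{name}: config must be a mapping")
        unknown = set(source) - set(DEFAULTS)
        if unknown:
            raise ConfigError(f"{name}: unknown config keys {sorted(unknown)}")
        cfg.update({k: v for k, v in source.items() if v is not None})
    return cfg


def dump_effective_config(cfg: dict, out_dir: str) -> None:
    """Serialize the effective configuration alongside the run outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = {"version": __version__, "config": cfg}
    (out / "config_used.json").write_text(json.dumps(blob, indent=2, sort_keys=True))
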