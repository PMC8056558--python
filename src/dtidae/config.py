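"""Flat YAML configuration mapped onto :class:`TrainingConfig`.

An empty (or absent-key) file yields the full default configuration; unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .autoencoder import TrainingConfig

__all__ = ["load_config", "save_config", "config_from_mapping"]

_FIELDS = {f.name: f for f in dataclasses.fields(TrainingConfig)}


def config_from_mapping(mapping: dict) -> TrainingConfig:
    unknown = set(mapping) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        if key == "hidden_sizes":
            if not isinstance(value, (list, tuple)):
                raise ValueError("hidden_sizes must be a list of integers")
            value = tuple(int(v) for v in value)
        elif key in ("zeros_are_observed", "regularize_biases"):
            if not isinstance(value, bool):
                raise ValueError(f"{key} must be a boolean")
        elif key in ("batch_size", "epochs", "seed"):
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValueError(f"{key} must be an integer")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError(f"{key} must be a number")
            value = float(value)
        kwargs[key] = value
    return TrainingConfig(**kwargs)


def load_config(path: str | Path | None) -> TrainingConfig:
    """Read a flat key/value YAML file; missing keys take defaults."""
    if path is None:
        return TrainingConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a flat key/value mapping")
    return config_from_mapping(raw)


def save_config(config: TrainingConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["hidden_sizes"] = list(config.hidden_sizes)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
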