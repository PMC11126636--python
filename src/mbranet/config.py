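"""YAML configuration loading with CLI-style overrides."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .training import TrainConfig

_TUPLE_FIELDS = ("betas", "lambdas")


def load_train_config(path=None, **overrides) -> TrainConfig:
    """Build a TrainConfig from an optional YAML file plus overrides.

    Unknown keys in the file are rejected so typos fail loudly.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(TrainConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS:
        if key in values:
            values[key] = tuple(values[key])
    return TrainConfig(**values)


def dump_train_config(config: TrainConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))
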