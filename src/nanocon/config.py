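"""YAML run configuration: defaults, schema validation, round-tripping.

A run configuration merges the architecture (:class:`ModelConfig`) and the
optimisation schedule (:class:`TrainConfig`, which carries the loss settings
alpha and margin) with a seed and optional file paths.  Unknown keys are
rejected by name so typos fail loudly before any compute; every field left
out takes its documented default, so an empty file is a valid all-defaults
configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}
_TRAIN_FIELDS = {f.name for f in dataclasses.fields(TrainConfig)}
_PATH_KEYS = {"features", "validation", "test", "checkpoint", "out"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted settings for one run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "train": dataclasses.asdict(self.train),
            "seed": self.seed,
            "paths": dict(self.paths),
        }


def _build_section(cls, fields: set[str], section: dict, name: str):
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}' section: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' configuration: {exc}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Top-level keys may be the ``model`` / ``train`` / ``seed`` / ``paths``
    sections, or any bare ModelConfig / TrainConfig field name (e.g.
    ``alpha: 0.8``), which is routed to its section.  Anything else is a
    :class:`ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    model_kw = dict(raw.pop("model", {}) or {})
    train_kw = dict(raw.pop("train", {}) or {})
    seed = raw.pop("seed", 0)
    paths = dict(raw.pop("paths", {}) or {})
    for key in list(raw):
        if key in _TRAIN_FIELDS:
            train_kw.setdefault(key, raw.pop(key))
        elif key in _MODEL_FIELDS:
            model_kw.setdefault(key, raw.pop(key))
        elif key in _PATH_KEYS:
            paths.setdefault(key, raw.pop(key))
    if raw:
        raise ConfigError(f"unknown configuration key(s): {sorted(raw)}")
    unknown_paths = set(paths) - _PATH_KEYS
    if unknown_paths:
        raise ConfigError(f"unknown path key(s): {sorted(unknown_paths)}")
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    model = _build_section(ModelConfig, _MODEL_FIELDS, model_kw, "model")
    train = _build_section(TrainConfig, _TRAIN_FIELDS, train_kw, "train")
    return RunConfig(model=model, train=train, seed=seed, paths=paths)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (load_config inverse)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
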