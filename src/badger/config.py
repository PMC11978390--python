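"""Run configuration: nested dataclasses loaded from YAML/JSON with strict
key checking and the published default hyperparameters (lr 1e-4, batch 64,
100 epochs, α 0.05)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .experiment import SplitSpec, TrainConfig
from .network import ModelConfig
from .objectives_metrics import DEFAULT_K_LIST, DEFAULT_REF_SIZE

__all__ = ["RunConfig", "PathsConfig", "MetricConfig", "load_config",
           "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or ill-typed values in a config file."""


@dataclass
class PathsConfig:
    perturbations: Optional[str] = None
    pathways: Optional[str] = None
    basal: Optional[str] = None
    drug_targets: Optional[str] = None
    target_pathways: Optional[str] = None
    out_dir: str = "badger_out"


@dataclass
class MetricConfig:
    ref_size: int = DEFAULT_REF_SIZE
    k_list: Sequence[int] = field(default_factory=lambda: list(DEFAULT_K_LIST))


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    paths: PathsConfig = field(default_factory=PathsConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.type in (
                ModelConfig, TrainConfig, SplitSpec, PathsConfig, MetricConfig):
            kwargs[key] = _build(f.type, value, f"{where}.{key}")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_SECTIONS = {"model": ModelConfig, "train": TrainConfig, "split": SplitSpec,
             "paths": PathsConfig, "metrics": MetricConfig}


def load_config(path) -> RunConfig:
    """Load YAML or JSON; missing sections/keys fall back to defaults,
    unknown keys are rejected by name."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") \
        else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top level of a config file must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {name: _build(cls, data[name], name)
              for name, cls in _SECTIONS.items() if name in data}
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    blob = {name: dataclasses.asdict(getattr(cfg, name))
            for name in _SECTIONS}
    blob["metrics"]["k_list"] = list(blob["metrics"]["k_list"])
    Path(path).write_text(yaml.safe_dump(blob, sort_keys=False))
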