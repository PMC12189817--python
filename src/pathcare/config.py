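"""Declarative run configuration.

A single YAML file with nested sections mirrors the library configs::

    seed: 42            # global seed, propagated to unset section seeds
    out_dir: runs/demo
    synth:      {n_patients: 2000, prevalence: 0.13, ...}
    model:      {hidden_dim: 64, gate_dim: 64, alpha: 0.1, variant: full}
    train:      {batch_size: 256, max_epochs: 100, patience: 10, ...}
    evaluation: {n_boot: 1000, task: mortality}
    max_T: 10           # optional visit-count truncation

Unknown keys anywhere are rejected before any computation.  Command-line
overrides take precedence over the file, which takes precedence over
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import yaml

from .model import ModelConfig
from .synth import SynthConfig
from .train import TrainConfig


@dataclass
class EvalConfig:
    n_boot: int = 1000
    task: str = "mortality"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


class ConfigError(ValueError):
    """A configuration file or override violates the schema."""


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "runs/pathcare"
    max_T: Optional[int] = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: Dict[str, Any] = field(default_factory=dict)  # n_features derived
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def model_config(self, n_features: int) -> ModelConfig:
        return ModelConfig(n_features=n_features, **self.model)

    def to_dict(self) -> Dict[str, Any]:
        d = {"seed": self.seed, "out_dir": self.out_dir, "max_T": self.max_T,
             "synth": dataclasses.asdict(self.synth),
             "model": dict(self.model),
             "train": dataclasses.asdict(self.train),
             "evaluation": dataclasses.asdict(self.evaluation)}
        return d

    def hash(self) -> str:
        """Stable digest of the config, stamped into every artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_section(cls, data: Dict[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: "
                          f"{sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid value in section {name!r}: {e}") from e


def load_config(path: Optional[str] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Load and validate a run config; precedence CLI > file > defaults."""
    data: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = value
        else:
            data[key] = value

    known_top = {"seed", "out_dir", "max_T", "synth", "model", "train",
                 "evaluation"}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    seed = int(data.get("seed", 42))
    synth_d = dict(data.get("synth") or {})
    train_d = dict(data.get("train") or {})
    model_d = dict(data.get("model") or {})
    synth_d.setdefault("seed", seed)
    train_d.setdefault("seed", seed)
    model_d.setdefault("init_seed", seed)
    if "n_features" in model_d:
        raise ConfigError("model.n_features is derived from the data; "
                          "set synth.n_features instead")
    # validate model keys against ModelConfig (with a placeholder dim)
    _build_section(ModelConfig, {"n_features": 1, **model_d}, "model")

    return RunConfig(
        seed=seed,
        out_dir=str(data.get("out_dir", "runs/pathcare")),
        max_T=None if data.get("max_T") is None else int(data["max_T"]),
        synth=_build_section(SynthConfig, synth_d, "synth"),
        model=model_d,
        train=_build_section(TrainConfig, train_d, "train"),
        evaluation=_build_section(EvalConfig,
                                  dict(data.get("evaluation") or {}),
                                  "evaluation"),
    )
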