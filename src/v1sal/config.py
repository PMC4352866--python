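"""Pipeline configuration: one validated record of every tunable setting."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sparse_net import TrainingConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables across the pipeline, loadable from YAML/JSON.

    Defaults mirror the model's standard settings: 14x14 patches, 128
    neurons, 1000 histogram bins, 256 entropy quantization levels.
    Unknown keys in a config file are rejected.
    """

    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_train_patches: int = 50_000
    bins: int = 1000
    hist_eps: float = 1.0
    prob_model: str = "hist"          # "hist" or "ggd"
    entropy_levels: int = 256
    stride: int = 1
    smooth_sigma: float = 0.0
    linearize_srgb: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.prob_model not in ("hist", "ggd"):
            raise ValueError("prob_model must be 'hist' or 'ggd'")
        if self.bins < 1 or self.entropy_levels < 1 or self.stride < 1:
            raise ValueError("bins, entropy_levels and stride must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "training" in data and isinstance(data["training"], dict):
            tknown = {f.name for f in dataclasses.fields(TrainingConfig)}
            tunknown = set(data["training"]) - tknown
            if tunknown:
                raise ValueError(f"unknown training config keys: {sorted(tunknown)}")
            data["training"] = TrainingConfig(**data["training"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
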