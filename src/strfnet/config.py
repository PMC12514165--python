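"""Experiment configuration: a versioned YAML schema tying modules together.

A config file fully determines an experiment: the synthetic recipe (or a
dataset path), the model specification, the training protocol, and the
interpretation settings.  Re-running a saved config with the same seeds
reproduces the results exactly (all computation is single-threaded numpy).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .nets.encoder import ModelSpec
from .training import TbpttConfig, TrainConfig

SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    synthetic: dict = field(default_factory=lambda: {
        "n_neurons": 5, "F": 16, "W": 10, "T": 400, "n_clips": 10, "M": 10,
        "adaptation": "none", "tau": 100.0, "gamma": 0.0,
        "noise_model": "gaussian", "noise_sigma": 0.1, "seed": 0,
    })
    dataset_path: str | None = None
    model: dict = field(default_factory=lambda: {
        "architecture": "statenet", "core": "gru", "hidden": 16,
    })
    train: dict = field(default_factory=dict)
    interpret: dict = field(default_factory=lambda: {
        "horizon": 50, "n_iters": 1500, "lr": 1e-2,
    })
    seeds: list[int] = field(default_factory=lambda: [0])
    out_dir: str = "strfnet_out"
    version: int = SCHEMA_VERSION

    def model_spec(self, n_freqs: int, n_neurons: int) -> ModelSpec:
        return ModelSpec(n_freqs=n_freqs, n_neurons=n_neurons, **self.model)

    def train_config(self, seed: int) -> TrainConfig:
        kw = dict(self.train)
        tb = kw.pop("tbptt", None)
        cfg = TrainConfig(seed=seed, **kw)
        if tb is not None:
            cfg.tbptt = TbpttConfig(**tb)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if data.get("version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValueError(f"unsupported config version {data.get('version')}")
        return cls(**data)
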