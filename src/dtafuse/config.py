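"""Run configuration: dataset presets, YAML (de)serialisation, seeds.

Presets select the benchmark hyperparameter columns (``davis``, ``kiba``,
``bindingdb``) or the desk-scale ``synthetic`` profile whose widths and
budgets are sized for CPU-only runs on generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import SyntheticSpec
from .model import ModelConfig
from .training import TrainConfig

_BENCH_COMMON = dict(embedding_dim=128, se_reduction=16, gin_depth=5, gin_hidden=128,
                     gin_out=128, attn_dim=128, heads=8, mlp_hidden=(1024, 1024, 512),
                     dropout=0.2)

PRESETS: dict = {
    "davis": {
        "model": dict(_BENCH_COMMON, smiles_filters=(16, 32, 48),
                      protein_filters=(16, 32, 48), max_smiles_len=100,
                      max_protein_len=1000),
        "train": dict(epochs=600, learning_rate=1e-4, batch_size=512),
    },
    "kiba": {
        "model": dict(_BENCH_COMMON, smiles_filters=(32, 64, 96),
                      protein_filters=(32, 64, 96), max_smiles_len=100,
                      max_protein_len=1000),
        "train": dict(epochs=600, learning_rate=1e-4, batch_size=1024),
    },
    "bindingdb": {
        "model": dict(_BENCH_COMMON, smiles_filters=(32, 64, 96),
                      protein_filters=(32, 64, 96), max_smiles_len=100,
                      max_protein_len=1000),
        "train": dict(epochs=600, learning_rate=1e-4, batch_size=1024),
    },
    # Desk-scale profile for the synthetic planted-signal benchmark.
    "synthetic": {
        "model": dict(max_smiles_len=64, max_protein_len=64, embedding_dim=32,
                      smiles_filters=(16, 32), protein_filters=(16, 32),
                      smiles_kernel=4, protein_kernel=6, se_reduction=4,
                      gin_depth=3, gin_hidden=32, gin_out=32, attn_dim=32,
                      heads=2, mlp_hidden=(128, 128, 64), dropout=0.1),
        "train": dict(epochs=60, learning_rate=3e-3, batch_size=64),
    },
}


def model_config(preset: str = "synthetic", seed: int = 0, **overrides) -> ModelConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return ModelConfig(**{**PRESETS[preset]["model"], "seed": seed, **overrides})


def train_config(preset: str = "synthetic", seed: int = 0, **overrides) -> TrainConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return TrainConfig(**{**PRESETS[preset]["train"], "seed": seed, **overrides})


@dataclass
class RunConfig:
    """Everything needed to re-run a command deterministically."""

    preset: str = "synthetic"
    seed: int = 0
    data_path: str | None = None
    columns: dict = field(default_factory=dict)
    out_dir: str = "runs/out"
    model: ModelConfig = None
    train: TrainConfig = None
    synthetic: SyntheticSpec = None

    def __post_init__(self):
        if self.model is None:
            self.model = model_config(self.preset, seed=self.seed)
        if self.train is None:
            self.train = train_config(self.preset, seed=self.seed)
        if self.synthetic is None:
            self.synthetic = SyntheticSpec(seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "data_path": self.data_path,
            "columns": dict(self.columns),
            "out_dir": self.out_dir,
            "model": self.model.to_dict(),
            "train": self.train.to_dict(),
            "synthetic": self.synthetic.to_dict(),
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        preset = d.get("preset", "synthetic")
        seed = int(d.get("seed", 0))
        model_overrides = d.get("model") or {}
        train_overrides = d.get("train") or {}
        synth = d.get("synthetic") or {}
        model = ModelConfig.from_dict({**PRESETS[preset]["model"],
                                       **model_overrides, "seed": seed})
        train = TrainConfig(**{**PRESETS[preset]["train"],
                               **train_overrides, "seed": seed})
        synth_kwargs = dict(synth)
        for key in ("fragment_pool", "protein_alphabet"):
            if key in synth_kwargs:
                synth_kwargs[key] = tuple(synth_kwargs[key])
        synthetic = SyntheticSpec(**{**synth_kwargs, "seed": synth_kwargs.get("seed", seed)})
        return cls(preset=preset, seed=seed, data_path=d.get("data_path"),
                   columns=d.get("columns") or {}, out_dir=d.get("out_dir", "runs/out"),
                   model=model, train=train, synthetic=synthetic)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def resolve_config(config_path=None, preset=None, seed=None, out_dir=None) -> RunConfig:
    """Merge a YAML file (if given) with CLI-level overrides."""
    if config_path is not None:
        cfg = RunConfig.load(config_path)
    else:
        cfg = RunConfig(preset=preset or "synthetic", seed=seed or 0)
    if preset is not None and config_path is not None and preset != cfg.preset:
        cfg = RunConfig.from_dict({**cfg.to_dict(), "preset": preset,
                                   "model": {}, "train": {}})
    if seed is not None:
        d = cfg.to_dict()
        d["seed"] = seed
        d["synthetic"]["seed"] = seed
        cfg = RunConfig.from_dict(d)
    if out_dir is not None:
        cfg.out_dir = str(out_dir)
    Path(cfg.out_dir)  # validate it is path-like
    return cfg
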