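"""Schema-validated run configuration for the command-line interface."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .datasets import BlockGeometry
from .errors import ConfigError
from .model import MINI_CONFIG, ModelConfig
from .synthetic import GrammarSpec
from .training import MINI_SCHEDULE, TrainingSchedule


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    out_dir: str = "runs/default"
    genome: str | None = None
    annotation: str | None = None
    evidence: str | None = None
    samples: str | None = None
    site_table: str | None = None
    variants: str | None = None
    checkpoints: str | None = None


class SimulateConfig(_Strict):
    n_genes: int = 250
    depth: int = 100
    n_samples: int = 8


class GeometryConfig(_Strict):
    flank: int = 250
    step: int = 1000

    def build(self) -> BlockGeometry:
        return BlockGeometry(flank=self.flank, step=self.step)


class ModelSection(_Strict):
    n_residual_blocks: int = MINI_CONFIG.n_residual_blocks
    channels: int = MINI_CONFIG.channels
    kernels: list[int] = list(MINI_CONFIG.kernels)
    dilations: list[int] = list(MINI_CONFIG.dilations)
    skip_taps: list[int] = list(MINI_CONFIG.skip_taps)

    def build(self) -> ModelConfig:
        return ModelConfig(n_residual_blocks=self.n_residual_blocks,
                           channels=self.channels,
                           kernels=tuple(self.kernels),
                           dilations=tuple(self.dilations),
                           skip_taps=tuple(self.skip_taps))


class ScheduleSection(_Strict):
    pretrain_cycles: list[int] = list(MINI_SCHEDULE.pretrain_cycles)
    pretrain_lr: float = MINI_SCHEDULE.pretrain_lr
    tissue_epochs: int = MINI_SCHEDULE.tissue_epochs
    tissue_lr: float = MINI_SCHEDULE.tissue_lr
    finetune_epochs: int = MINI_SCHEDULE.finetune_epochs
    finetune_lr: float = MINI_SCHEDULE.finetune_lr
    label_smoothing: float = MINI_SCHEDULE.label_smoothing
    batch_size: int = MINI_SCHEDULE.batch_size
    holdout_fraction: float = MINI_SCHEDULE.holdout_fraction
    patience: int | None = MINI_SCHEDULE.patience
    weight_decay: float = MINI_SCHEDULE.weight_decay
    ensemble_size: int = MINI_SCHEDULE.ensemble_size
    finetune_ensemble_size: int = MINI_SCHEDULE.finetune_ensemble_size

    def build(self) -> TrainingSchedule:
        d = self.model_dump()
        d["pretrain_cycles"] = tuple(d["pretrain_cycles"])
        return TrainingSchedule(**d)


class RunConfig(_Strict):
    seed: int = 0
    paths: PathsConfig = PathsConfig()
    simulate: SimulateConfig = SimulateConfig()
    geometry: GeometryConfig = GeometryConfig()
    model: ModelSection = ModelSection()
    schedule: ScheduleSection = ScheduleSection()
    test_chroms: list[str] = ["chr1", "chr3"]


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
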