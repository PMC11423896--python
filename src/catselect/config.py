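"""Structured pipeline configuration with strict YAML round-tripping.

Unknown keys are rejected (with their full key path), every section is a
typed dataclass, and each pipeline stage derives its random seed
deterministically from the single global seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .encoding import EncodingConfig
from .geometry import GeometryConfig
from .localizer import LocalizerDesign
from .planted import PlantedModelConfig
from .readout import ReadoutConfig
from .stimuli import StimulusConfig
from .voxels import VoxelConfig

SCHEMA_VERSION = 1

#: fixed stage order; also the per-stage seed derivation index
STAGES = ("simulate", "localize", "readout", "lesion", "voxels", "encode",
          "geometry")


class ConfigError(ValueError):
    """Schema violation in a pipeline configuration."""


@dataclass
class LesionRunConfig:
    n_top: int = 2          # categories quantified in the cross-validated deficit
    k: int = 1              # top-k for accuracy
    n_random_draws: int = 5
    top_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_top < 1 or self.k < 1 or self.n_random_draws < 1:
            raise ConfigError("lesion counts must be >= 1")


@dataclass
class PipelineConfig:
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    model: PlantedModelConfig = field(default_factory=PlantedModelConfig)
    localizer: LocalizerDesign = field(default_factory=LocalizerDesign)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    lesion: LesionRunConfig = field(default_factory=LesionRunConfig)
    voxels: VoxelConfig = field(default_factory=VoxelConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([int(self.seed), STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _build(f.type, val, f"{path}.{f.name}")
        kwargs[f.name] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    "stimuli": StimulusConfig,
    "model": PlantedModelConfig,
    "localizer": LocalizerDesign,
    "readout": ReadoutConfig,
    "lesion": LesionRunConfig,
    "voxels": VoxelConfig,
    "encoding": EncodingConfig,
    "geometry": GeometryConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - (set(_SECTION_TYPES) | {"seed", "schema_version"})
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version {version} != supported {SCHEMA_VERSION}"
        )
    kwargs = {"seed": int(data.get("seed", 0)), "schema_version": SCHEMA_VERSION}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = dict(data[name])
            # YAML maps tuples to lists; coerce the tuple-typed fields back
            for key in ("scrambled_splits",):
                if key in section and isinstance(section[key], list):
                    section[key] = tuple(section[key])
            kwargs[name] = _build(cls, section, name)
    cfg = PipelineConfig(**kwargs)
    validate_config(cfg)
    return cfg


def validate_config(cfg: PipelineConfig) -> None:
    cfg.stimuli.validate()
    cfg.model.validate()
    cfg.lesion.validate()
    cfg.voxels.validate()
    if cfg.encoding.alpha < 0:
        raise ConfigError("encoding.alpha must be >= 0")
    if cfg.encoding.ncsnr_threshold < 0:
        raise ConfigError("encoding.ncsnr_threshold must be >= 0")
    cfg.geometry.validate()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    try:
        return config_from_dict(data)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path
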