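"""Run configuration: one nested, YAML-serializable record for every stage.

Unknown keys are rejected and every value is range-checked by the module
dataclasses' own ``__post_init__`` validators, so a typo in a config file
fails at load time rather than mid-run.  All randomness derives from the
single ``seed`` field, fanned out per stage by a fixed counter offset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .model import ModelConfig
from .postprocess import PostprocessConfig
from .synth import SynthParams
from .train import AugmentParams, LossConfig, TrainConfig


@dataclass(frozen=True)
class StainConfig:
    sparsity_weight: float = 0.1
    target: str = ""          # path of the stain-reference tile ("" = first train tile)
    enabled: bool = True

    def __post_init__(self):
        if self.sparsity_weight < 0:
            raise InvalidParameterError("sparsity_weight must be >= 0")


@dataclass(frozen=True)
class MaskConfig:
    contour_thickness: int = 2
    white_threshold: float = 220.0

    def __post_init__(self):
        if self.contour_thickness < 1:
            raise InvalidParameterError("contour_thickness must be >= 1")
        if not (0 < self.white_threshold < 255):
            raise InvalidParameterError("white_threshold must lie in (0, 255)")


# per-stage seed offsets (single global seed fans out deterministically)
SEED_OFFSETS = {"synth": 1, "stain": 2, "split": 3, "train": 4, "augment": 5}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    n_tiles: int = 40
    n_test_tiles: int = 10
    stain: StainConfig = field(default_factory=StainConfig)
    masks: MaskConfig = field(default_factory=MaskConfig)
    synth: SynthParams = field(default_factory=SynthParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + SEED_OFFSETS[stage]) % (2**31)


_TUPLE_FIELDS = {"block_layers", "decoder_channels", "betas",
                 "gland_radius_range"}

# SynthParams.stain_basis is a StainBasis object; it is not configured via
# YAML (the generator default is the reference H&E basis)
_SKIP_FIELDS = {"stain_basis"}


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        if f.name in _SKIP_FIELDS:
            continue
        value = getattr(obj, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = _to_dict(value)
        elif isinstance(value, tuple):
            out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise InvalidParameterError(f"expected a mapping for {cls.__name__}")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise InvalidParameterError(
            f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    defaults = cls()  # every config dataclass is fully defaulted
    kwargs = {}
    for name, value in data.items():
        current = getattr(defaults, name)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            kwargs[name] = _from_dict(type(current), value)
        elif name in _TUPLE_FIELDS and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)
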