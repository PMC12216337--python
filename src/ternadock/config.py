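"""YAML-backed run configuration.

One :class:`RunConfig` gathers the per-stage config blocks.  Defaults
encode the documented operating point: quality gates 3.5 A / R-free 0.26,
>= 3 contacts at 4 A, clash below 2 A, noise level 2, a 50-conformation
training pool, 40 inference conformers for PROTACs and 1 for molecular
glues, and the acceptable-rank sentinel 41.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curation import CurationConfig
from .decoder import DecoderConfig
from .encoder import EncoderConfig
from .errors import ConfigError
from .featurize import FeaturizerConfig
from .inference import InferenceConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."
    curation: CurationConfig = field(default_factory=CurationConfig)
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)


_BLOCKS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError, Exception) as exc:  # dataclass validation
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid {context} config: {exc}") from exc


def _validate(config: RunConfig) -> RunConfig:
    if config.featurizer.noise_level < 0:
        raise ConfigError("featurizer.noise_level must be >= 0")
    if config.train.noise_level < 0:
        raise ConfigError("train.noise_level must be >= 0")
    if config.train.conformer_pool_size < 1:
        raise ConfigError("train.conformer_pool_size must be >= 1")
    return config


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = all defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key not in _BLOCKS:
            raise ConfigError(f"unknown top-level key {key!r}")
        f = _BLOCKS[key]
        if dataclasses.is_dataclass(f.default_factory) or key in (
                "curation", "featurizer", "encoder", "decoder", "train", "inference"):
            if not isinstance(value, dict):
                raise ConfigError(f"{key} must be a mapping")
            if key == "curation" and "buffer_codes" in value:
                value = dict(value)
                value["buffer_codes"] = frozenset(value["buffer_codes"])
            kwargs[key] = _build(f.default_factory, value, key)
        else:
            kwargs[key] = value
    return _validate(RunConfig(**kwargs))


def dump_config(config: RunConfig, path) -> None:
    def as_plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: as_plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, (list, tuple)):
            return [as_plain(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(as_plain(config), sort_keys=False))
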