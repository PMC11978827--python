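"""YAML run configuration: nested dataclass schema with strict key checking.

Unknown keys are rejected with the offending key named and, where possible, a
close-match suggestion.  An empty file yields all defaults (w=64, s=32, h=2,
n_roi=6, lr=1e-4, conv kernel 32 / stride 16, 224 x 224 images).
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .fusion_losses import LossConfig
from .synthetic_data import SyntheticConfig
from .timeformer import TimeformerConfig
from .training_eval import TrainConfig

__all__ = ["RunConfig", "PathsConfig", "ConfigError", "load_config", "save_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Schema violation; message names the offending key."""


@dataclass
class PathsConfig:
    data_dir: str = "data"
    out_dir: str = "run"


@dataclass
class ModelSection:
    d: int = 32
    conv_kernel: int = 32
    conv_stride: int = 16


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    timeformer: TimeformerConfig = field(default_factory=TimeformerConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelSection = field(default_factory=ModelSection)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, prefix: str):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1, cutoff=0.5)
            if not hint:  # fall back to prefix matches ("width" -> "w")
                hint = [k for k in known if key.startswith(k) or k.startswith(key)]
            suggestion = f'; did you mean "{hint[0]}"?' if hint else ""
            raise ConfigError(f'unknown config key "{prefix}{key}"{suggestion}')
        ftype = known[key].type
        if isinstance(value, dict):
            sub = known[key].default_factory if known[key].default_factory is not dataclasses.MISSING else None
            if sub is None:
                raise ConfigError(f'"{prefix}{key}" does not accept a mapping')
            kwargs[key] = _build(type(sub()), value, f"{prefix}{key}.")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under {prefix.rstrip('.') or 'config'}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file; missing keys take defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = _build(RunConfig, data, "")
    # keep the shared feature dimension consistent across sections
    cfg.timeformer.d = cfg.model.d
    logger.info("effective config: %s", cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
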