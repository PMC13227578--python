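"""Run configuration: a validated, YAML/JSON-serializable bundle of every
tunable in the pipeline.  Unknown keys are rejected and out-of-range values
raise a :class:`ConfigError` naming the offending key."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import ViTConfig
from .preprocess import AugmentSpec
from .train import TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key(s)."""


class AugmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rotation_deg: float = 20.0
    hflip_prob: float = Field(0.5, ge=0.0, le=1.0)
    zoom_factor: float = Field(1.1, gt=0.0)
    shift_x: int = 10
    shift_y: int = -5
    brightness: float = Field(1.2, gt=0.0)
    contrast: float = Field(1.5, gt=0.0)
    factor: int = Field(5, ge=1)  # dataset expansion multiplicity

    def to_spec(self, seed: int = 0, deterministic: bool = False) -> AugmentSpec:
        return AugmentSpec(
            rotation_deg=self.rotation_deg,
            hflip_prob=self.hflip_prob,
            zoom_factor=self.zoom_factor,
            shift_x=self.shift_x,
            shift_y=self.shift_y,
            brightness=self.brightness,
            contrast=self.contrast,
            seed=seed,
            deterministic=deterministic,
        )


class RunConfig(BaseModel):
    """All pipeline tunables with their defaults."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    # image / model geometry
    image_height: int = Field(64, ge=8)
    image_width: int = Field(64, ge=8)
    patch_size: int = Field(16, ge=1)
    embed_dim: int = Field(32, ge=2)
    depth: int = Field(2, ge=0)
    heads: int = Field(2, ge=1)
    num_classes: int = Field(4, ge=2)
    use_positional: bool = True
    positional: str = "1d"
    use_cross_attention: bool = False
    cross_source: int = Field(0, ge=0)

    # training
    lam: float = Field(0.5, ge=0.0, alias="lambda")
    learning_rate: float = Field(1e-3, gt=0.0)
    weight_decay: float = Field(0.0, ge=0.0)
    batch_size: int = Field(16, ge=1)
    max_epochs: int = Field(20, ge=1)
    patience: int = Field(5, ge=1)
    min_improvement: float = Field(1e-4, ge=0.0)
    seed: int = 0
    severity_range: float = Field(3.0, gt=0.0)

    # evaluation
    area_quantile: float = Field(0.9, ge=0.0, lt=1.0)

    augment: AugmentConfig = AugmentConfig()

    def vit_config(self) -> ViTConfig:
        return ViTConfig(
            image_size=(self.image_height, self.image_width),
            patch_size=self.patch_size,
            embed_dim=self.embed_dim,
            depth=self.depth,
            heads=self.heads,
            num_classes=self.num_classes,
            use_positional=self.use_positional,
            positional=self.positional,
            use_cross_attention=self.use_cross_attention,
            cross_source=self.cross_source,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            model=self.vit_config(),
            lam=self.lam,
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_improvement=self.min_improvement,
            seed=self.seed,
            severity_range=self.severity_range,
        )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML or JSON run config; an empty/missing file gives all
    defaults.  Unknown keys or out-of-range values raise ConfigError."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    data.update(overrides)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config (keys: {keys}): {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the config; .json gets JSON, anything else YAML.  Round-trips
    exactly through :func:`load_config`."""
    payload = cfg.model_dump(by_alias=True)
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(payload, indent=2))
    else:
        p.write_text(yaml.safe_dump(payload, sort_keys=False))
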