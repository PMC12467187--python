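"""YAML run configuration with strict validation.

Unknown keys are rejected (naming the key); missing sections fall back to
defaults. The canonical serialised form round-trips exactly, and its
SHA-256 hash stamps every run output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .types import ConfigError

__all__ = ["RunConfig", "load_config", "loads_config", "dump_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    image_size: tuple[int, int] = (128, 128)
    n_instances: tuple[int, int] = (2, 6)
    radius_range: tuple[float, float] = (5.0, 24.0)
    bud_radius_fraction: float = 0.4
    blur_sigma: float = 1.2
    noise_std: float = 0.03
    max_overlap_iou: float = 0.3
    class_weights: dict[str, float] = {
        "cyst": 0.35, "early_organoid": 0.30, "late_organoid": 0.10,
        "spheroid": 0.25}


class DetectorSection(_Strict):
    num_classes: int = 4
    strides: tuple[int, ...] = (8, 16, 32)
    neck_channels: int = 24
    backbone_widths: tuple[int, ...] = (8, 16, 24, 32, 48)
    anchors: int = 1
    kernel_size: int = 11
    dilation: int = 2
    activation: str = "sigmoid"
    heads: int = 4
    gn_groups: int | None = None
    score_threshold: float = 0.05
    nms_iou_threshold: float = 0.6

    @field_validator("dilation")
    @classmethod
    def _dil(cls, v):
        if v != 2:
            raise ValueError("dilation rate is fixed at 2")
        return v

    @field_validator("activation")
    @classmethod
    def _act(cls, v):
        if v not in ("sigmoid", "silu"):
            raise ValueError(f"activation must be sigmoid or silu, got {v!r}")
        return v


class ScheduleSection(_Strict):
    epochs: int = 32
    lr: float = 2e-3
    batch_size: int = 8
    weight_decay: float = 1e-4


class EvalSection(_Strict):
    iou_thr: float = 0.5
    score_thr: float = 0.3


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs"
    n_images: int = 300
    scene: SceneSection = SceneSection()
    detector: DetectorSection = DetectorSection()
    schedule: ScheduleSection = ScheduleSection()
    eval: EvalSection = EvalSection()


def loads_config(text: str) -> RunConfig:
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return RunConfig(**data)
    except ValidationError as err:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in err.errors())
        raise ConfigError(f"invalid configuration key(s): {keys}") from err


def load_config(path) -> RunConfig:
    return loads_config(Path(path).read_text())


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
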