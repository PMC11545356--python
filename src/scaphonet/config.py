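"""Run configuration: dataclasses, defaults and strict YAML validation.

The defaults reproduce the reference training protocol: stage 1 resized to
1400x1200 with SGD (5000 iterations, batch 1, lr 0.001, weight decay 1e-4,
momentum 0.9); stage 2 on 256x256 crops with Adam (1500 iterations, batch
12, lr 1e-4, weight decay 1e-4) and an anchor menu of aspect ratios
1/1.15/2/2.25/3 with scales 2^(i/5), i=0..4, over per-level sizes 9/4/1 px.
``scaled_run_config`` returns the desk-scale study conditions used by the
test-suite and the acceptance script (tiny backbone, 64 px crops, reduced
anchor menu and iteration counts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .fracture_net import ContextExtractorConfig, HeadConfig
from .geometry import AnchorGrid, build_anchor_grid
from .imaging import PreprocessConfig
from .locator import Stage1Config
from .phantom import PhantomConfig

__all__ = [
    "AnchorSpec", "Stage2TrainConfig", "Stage1TrainConfig", "InferenceConfig",
    "Stage2Config", "RunConfig", "ConfigError", "validate_config",
    "default_run_config", "scaled_run_config", "scaled_phantom_config",
    "stage1_config_to_json", "stage1_config_from_json",
]


class ConfigError(ValueError):
    """A named schema violation in a configuration file."""


@dataclass
class AnchorSpec:
    """Anchor menu: per-level strides/base sizes plus ratio and scale lists."""

    level_strides: tuple[int, ...] = (4, 8, 16)
    base_sizes: tuple[float, ...] = (9.0, 4.0, 1.0)
    aspect_ratios: tuple[float, ...] = (1.0, 1.15, 2.0, 2.25, 3.0)
    scales: tuple[float, ...] = (1.0, 2**0.2, 2**0.4, 2**0.6, 2**0.8)

    def grid(self, image_size: tuple[int, int]) -> AnchorGrid:
        return build_anchor_grid(image_size, self.level_strides,
                                 self.base_sizes, self.aspect_ratios,
                                 self.scales)

    def to_json(self) -> dict:
        return {"level_strides": list(self.level_strides),
                "base_sizes": list(self.base_sizes),
                "aspect_ratios": list(self.aspect_ratios),
                "scales": list(self.scales)}


@dataclass
class Stage2TrainConfig:
    iterations: int = 1500
    batch_size: int = 12
    lr: float = 1e-4
    weight_decay: float = 1e-4
    optimizer: str = "adam"
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    augment: bool = True
    hflip_probability: float = 0.5
    contrast_jitter: tuple[float, float] = (0.8, 1.2)
    # global gradient-norm ceiling; stabilizes the N_pos-normalized losses
    grad_clip: float = 20.0


@dataclass
class Stage1TrainConfig:
    iterations: int = 5000
    batch_size: int = 1
    lr: float = 1e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9
    pos_iou: float = 0.5
    neg_iou: float = 0.3
    grad_clip: float = 20.0


@dataclass
class InferenceConfig:
    """Stage-2 decoding and rescoring parameters.

    ``retain_rescore`` implements the final retention rule: a detection is
    reported only when its rescored value reaches 1.0, i.e. the fusion
    classification gate passed and the detector score contributes.  The NMS
    threshold and score floor are package defaults (unvalidated against the
    original system, which does not state them).
    """

    score_floor: float = 0.05
    nms_iou: float = 0.2
    top_k: int = 3
    cls_threshold: float = 0.5
    decision_threshold: float = 0.5
    retain_rescore: float = 1.0
    match_iou: float = 0.2


@dataclass
class Stage2Config:
    crop_size: int = 256
    crop_margin: float = 0.25
    # CLAHE re-applied on crops; the tile grid follows the crop size so the
    # equalization kernel stays ~32 px as in the full-scale setting
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    fpn_channels: int = 64
    backbone: BackboneConfig = field(default_factory=BackboneConfig.tiny)
    context: ContextExtractorConfig = field(default_factory=ContextExtractorConfig)
    anchors: AnchorSpec = field(default_factory=AnchorSpec)
    train: Stage2TrainConfig = field(default_factory=Stage2TrainConfig)
    infer: InferenceConfig = field(default_factory=InferenceConfig)

    def head_config(self) -> HeadConfig:
        return HeadConfig(
            len(self.anchors.aspect_ratios) * len(self.anchors.scales), 1)

    def anchor_grid(self) -> AnchorGrid:
        return self.anchors.grid((self.crop_size, self.crop_size))

    def anchor_json(self) -> dict:
        return self.anchors.to_json()


@dataclass
class RunConfig:
    """Top-level configuration; one global seed fans out to all components."""

    seed: int = 0
    out_dir: str = "runs/default"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage1_train: Stage1TrainConfig = field(default_factory=Stage1TrainConfig)
    stage2: Stage2Config = field(default_factory=Stage2Config)


def default_run_config() -> RunConfig:
    return RunConfig()


def scaled_phantom_config(seed: int = 0, n_fracture: int = 75,
                          n_normal: int = 100) -> PhantomConfig:
    """The phantom generator at its (already desk-scale) defaults."""
    return PhantomConfig(n_fracture=n_fracture, n_normal=n_normal, seed=seed)


def scaled_run_config(seed: int = 0) -> RunConfig:
    """Desk-scale study conditions: tiny profiles, 64 px crops, short runs.

    These are the conditions of the package's synthetic experiments: a
    192x192 phantom frame (~50 px scaphoid), stage-1 input resized to 96x96
    with base anchors 16/24/32, stage-2 crops of 64 px with elongated anchor
    ratios matched to thin fracture bars, and iteration counts sized for a
    single CPU.
    """
    cfg = RunConfig(seed=seed)
    cfg.preprocess = replace(cfg.preprocess, stage1_size=(96, 96),
                             stage2_size=(64, 64))
    cfg.stage1 = Stage1Config(
        input_size=(96, 96), base_sizes=(16.0, 24.0, 32.0),
        aspect_ratios=(0.8, 1.0, 1.25), scales=(1.0, 1.3),
        proposal_top_n=10)
    cfg.stage1_train = Stage1TrainConfig(iterations=1200, lr=3e-4)
    cfg.stage2 = Stage2Config(
        crop_size=64,
        clahe_clip=1.0,
        clahe_tiles=(2, 2),
        anchors=AnchorSpec(level_strides=(4, 8, 16),
                           base_sizes=(10.0, 16.0, 24.0),
                           aspect_ratios=(0.25, 0.4, 1.0, 2.5, 4.0),
                           scales=(1.0, 1.4)),
        train=Stage2TrainConfig(iterations=1500, batch_size=6,
                                lr=3e-4, weight_decay=2e-3,
                                pos_iou=0.25, neg_iou=0.15,
                                contrast_jitter=(0.9, 1.1)),
    )
    return cfg


# ---------------------------------------------------------------------------
# stage-1 config (de)serialization for checkpoints
# ---------------------------------------------------------------------------

def stage1_config_to_json(cfg: Stage1Config) -> dict:
    return {
        "input_size": list(cfg.input_size),
        "backbone": cfg.backbone.to_json(),
        "fpn_channels": cfg.fpn_channels,
        "level_strides": list(cfg.level_strides),
        "base_sizes": list(cfg.base_sizes),
        "aspect_ratios": list(cfg.aspect_ratios),
        "scales": list(cfg.scales),
        "proposal_top_n": cfg.proposal_top_n,
        "rpn_nms_iou": cfg.rpn_nms_iou,
        "score_floor": cfg.score_floor,
        "roi_size": cfg.roi_size,
        "roi_hidden": cfg.roi_hidden,
    }


def stage1_config_from_json(obj: dict) -> Stage1Config:
    return Stage1Config(
        input_size=tuple(obj["input_size"]),
        backbone=BackboneConfig.from_json(obj["backbone"]),
        fpn_channels=obj["fpn_channels"],
        level_strides=tuple(obj["level_strides"]),
        base_sizes=tuple(obj["base_sizes"]),
        aspect_ratios=tuple(obj["aspect_ratios"]),
        scales=tuple(obj["scales"]),
        proposal_top_n=obj["proposal_top_n"],
        rpn_nms_iou=obj["rpn_nms_iou"],
        score_floor=obj["score_floor"],
        roi_size=obj["roi_size"],
        roi_hidden=obj["roi_hidden"],
    )


# ---------------------------------------------------------------------------
# strict YAML loading
# ---------------------------------------------------------------------------

_TUPLE_FIELDS_FLOAT = {"contrast_jitter", "contrast_jitter_range",
                       "base_sizes", "aspect_ratios", "scales",
                       "scaphoid_size_range", "fracture_length_range",
                       "fracture_width_range", "fracture_contrast_range",
                       "bone_density_range", "branch_kernel_sizes",
                       "branch_dilation_rates"}


def _coerce(name: str, value, target):
    if dataclasses.is_dataclass(target) and not isinstance(target, type):
        return _build(type(target), value, name)
    if isinstance(target, tuple):  # default tuple value -> same length/type
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{name}: expected a list")
        if all(isinstance(t, int) for t in target) and name not in _TUPLE_FIELDS_FLOAT:
            if not all(isinstance(v, int) for v in value):
                raise ConfigError(f"{name}: expected integers")
            return tuple(value)
        if not all(isinstance(v, (int, float)) and not isinstance(v, bool)
                   for v in value):
            raise ConfigError(f"{name}: expected numbers")
        return tuple(float(v) for v in value)
    if isinstance(target, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{name}: expected a boolean")
        return value
    if isinstance(target, int):
        if not isinstance(value, int) or isinstance(value, bool):
            raise ConfigError(f"{name}: expected an integer")
        return value
    if isinstance(target, float):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{name}: expected a number")
        return float(value)
    if isinstance(target, str):
        if not isinstance(value, str):
            raise ConfigError(f"{name}: expected a string")
        return value
    raise ConfigError(f"{name}: unsupported value type")


def _build(cls, obj: dict | None, path: str = ""):
    instance = cls() if path else default_run_config()
    if obj is None:
        return instance
    if not isinstance(obj, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    updates = {}
    for key, value in obj.items():
        full = f"{path}.{key}" if path else key
        if key not in names:
            raise ConfigError(f"unknown configuration key {full!r}")
        updates[key] = _coerce(full, value, getattr(instance, key))
    try:
        return dataclasses.replace(instance, **updates)
    except ValueError as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def validate_config(path: str | Path | None) -> RunConfig:
    """Load and schema-check a YAML run configuration.

    An empty or absent file yields the full default configuration; unknown
    keys, wrong types and out-of-range values raise :class:`ConfigError`
    naming the offending key.
    """
    if path is None:
        return default_run_config()
    text = Path(path).read_text()
    obj = yaml.safe_load(text)
    if obj is None:
        return default_run_config()
    return _build(RunConfig, obj)
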