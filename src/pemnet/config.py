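"""Dataclass <-> dict <-> YAML round-tripping for all configuration types."""

from __future__ import annotations

import dataclasses

import yaml

from .gcam import GCAMConfig
from .model import ASPPConfig, BackboneSpec, PeMNetConfig, TrainConfig
from .view import ViewTrainConfig

__all__ = ["to_dict", "model_config_from_dict", "train_config_from_dict",
           "dump_yaml", "load_yaml"]


def _clean(obj):
    if isinstance(obj, tuple):
        return [_clean(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_clean(o) for o in obj]
    return obj


def to_dict(cfg) -> dict:
    return _clean(dataclasses.asdict(cfg))


def _tup(value):
    return None if value is None else tuple(value)


def model_config_from_dict(d: dict) -> PeMNetConfig:
    bb = d.get("backbone", {})
    backbone = BackboneSpec(
        name=bb.get("name", "tiny4"),
        stage_channels=_tup(bb.get("stage_channels", (16, 32, 64, 128))),
        stage_strides=_tup(bb.get("stage_strides", (1, 2, 2, 1))),
        stage_dilations=_tup(bb.get("stage_dilations")) if bb.get("stage_dilations") else None,
        stem_downsample=bb.get("stem_downsample", 4))
    if "gcam" in d:
        g = d["gcam"]
        # explicit null selects the attention-free baseline
        gcam = None if g is None else GCAMConfig(
            tap_channels=_tup(g.get("tap_channels", backbone.stage_channels)),
            r=g.get("r", 8.0),
            hidden_activation=g.get("hidden_activation", "relu"),
            output_activation=g.get("output_activation", "sigmoid"),
            bias_policy=g.get("bias_policy", "none"),
            final_projection=g.get("final_projection", "forbid"),
            normalize_taps=g.get("normalize_taps", False))
    else:
        gcam = GCAMConfig(tap_channels=backbone.stage_channels, normalize_taps=True)
    a = d.get("aspp", {})
    aspp = ASPPConfig(
        dilation_rates=_tup(a.get("dilation_rates", (6, 12, 18))),
        branch_channels=a.get("branch_channels", 32),
        separable=a.get("separable", True),
        image_pooling=a.get("image_pooling", True))
    return PeMNetConfig(backbone=backbone, gcam=gcam, aspp=aspp,
                        num_classes=d.get("num_classes", 2),
                        input_size=d.get("input_size", 128),
                        low_level_tap=d.get("low_level_tap", 0),
                        low_level_channels=d.get("low_level_channels", 8),
                        decoder_channels=d.get("decoder_channels", 32))


def train_config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    if d.get("class_weights") is not None:
        d["class_weights"] = tuple(d["class_weights"])
    return TrainConfig(**d)


def view_config_from_dict(d: dict) -> ViewTrainConfig:
    return ViewTrainConfig(**d)


def dump_yaml(data: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
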