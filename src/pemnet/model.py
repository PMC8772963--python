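"""Encoder-decoder segmentation network with GCAM-refined features.

The layout follows the Deeplabv3+ pattern: a staged convolutional encoder
at output stride 16, atrous spatial pyramid pooling (ASPP) with dilated
depthwise-separable branches on the final (attention-reweighted) features,
and a light decoder that upsamples, fuses a raw low-level skip from the
first stage and restores full resolution.  Backbones are desk-scale
channel-doubling stacks configured by :class:`BackboneSpec`; the GCAM taps
sit on the stage outputs.

Images enter on the 8-bit scale (0-255) as single-channel NCHW tensors.
The classifier head is zero-initialised, so an untrained model scores every
pixel as class 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gcam import GCAMChain, GCAMConfig
from .nn import Tensor, upsample_bilinear
from .nn.layers import Conv2d, Module, SeparableConv2d

__all__ = ["BackboneSpec", "ASPPConfig", "PeMNetConfig", "TrainConfig",
           "PeMNet", "build_model", "predict_mask", "predict_proba"]


@dataclass(frozen=True)
class BackboneSpec:
    """A channel-doubling residual-free stage stack.

    The stem downsamples by ``stem_downsample`` (default 4, i.e. feature
    maps at 0.25 height and width), then each stage applies two 3x3
    convolutions, the first with the stage's stride and dilation.
    """

    name: str = "tiny4"
    stage_channels: tuple = (16, 32, 64, 128)
    stage_strides: tuple = (1, 2, 2, 1)
    stage_dilations: tuple | None = None   # default: 1 except dilation 2 on
                                           # stride-1 stages after a stride-2 one
    stem_downsample: int = 4

    def __post_init__(self):
        object.__setattr__(self, "stage_channels", tuple(self.stage_channels))
        object.__setattr__(self, "stage_strides", tuple(self.stage_strides))
        if len(self.stage_channels) < 2:
            raise ValueError("need at least two stages")
        if len(self.stage_strides) != len(self.stage_channels):
            raise ValueError("stage_strides and stage_channels lengths differ")
        if any(s < 1 for s in self.stage_strides):
            raise ValueError("strides must be positive")
        if self.stem_downsample < 1 or (self.stem_downsample & (self.stem_downsample - 1)):
            raise ValueError("stem_downsample must be a positive power of two")
        if self.stage_dilations is None:
            dil, seen_stride = [], False
            for s in self.stage_strides:
                seen_stride = seen_stride or s > 1
                dil.append(2 if (s == 1 and seen_stride) else 1)
            object.__setattr__(self, "stage_dilations", tuple(dil))
        else:
            object.__setattr__(self, "stage_dilations", tuple(self.stage_dilations))

    @property
    def output_stride(self) -> int:
        return self.stem_downsample * int(np.prod(self.stage_strides))


@dataclass(frozen=True)
class ASPPConfig:
    dilation_rates: tuple = (6, 12, 18)
    branch_channels: int = 32
    separable: bool = True
    image_pooling: bool = True

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if len(set(rates)) != len(rates) or any(r < 1 for r in rates):
            raise ValueError("dilation rates must be distinct and >= 1")
        object.__setattr__(self, "dilation_rates", rates)


@dataclass(frozen=True)
class PeMNetConfig:
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    gcam: GCAMConfig | None = field(
        default_factory=lambda: GCAMConfig(tap_channels=(16, 32, 64, 128),
                                           normalize_taps=True))
    aspp: ASPPConfig = field(default_factory=ASPPConfig)
    num_classes: int = 2
    input_size: int = 128
    low_level_tap: int = 0
    low_level_channels: int = 8
    decoder_channels: int = 32

    def __post_init__(self):
        if self.gcam is not None:
            taps = self.gcam.tap_channels
            stages = self.backbone.stage_channels
            if len(taps) > len(stages) or stages[len(stages) - len(taps):] != taps:
                raise ValueError(
                    f"GCAM tap channels {list(taps)} are not a trailing run of "
                    f"backbone stage channels {list(stages)}")
        if not 0 <= self.low_level_tap < len(self.backbone.stage_channels):
            raise ValueError("low_level_tap out of range")

    @property
    def tap_start(self) -> int:
        if self.gcam is None:
            return len(self.backbone.stage_channels)
        return len(self.backbone.stage_channels) - len(self.gcam.tap_channels)


@dataclass(frozen=True)
class TrainConfig:
    """Training defaults for the segmentation model."""

    minibatch_size: int = 32
    initial_lr: float = 1e-4
    max_epochs: int = 50
    lr_drop_factor: float = 0.5
    lr_drop_period: int = 20
    shuffle_per_epoch: bool = True
    loss: str = "cross_entropy"
    class_weights: tuple | None = None   # optional imbalance handling, off by default
    seed: int = 0

    def __post_init__(self):
        if min(self.minibatch_size, self.max_epochs, self.lr_drop_period) < 1:
            raise ValueError("minibatch_size, max_epochs and lr_drop_period must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")


class _Stage(Module):
    def __init__(self, in_ch, out_ch, stride, dilation, rng):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=dilation,
                            dilation=dilation, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=dilation,
                            dilation=dilation, rng=rng)

    def forward(self, x):
        return self.conv2(self.conv1(x).relu()).relu()


class Backbone(Module):
    def __init__(self, spec: BackboneSpec, rng):
        self.spec = spec
        c0 = spec.stage_channels[0]
        # single strided stem conv (kernel just covering the stride)
        k = spec.stem_downsample + 1
        self.stem = [Conv2d(1, c0, k, stride=spec.stem_downsample,
                            padding=k // 2, rng=rng)]
        prev = c0
        self.stages = []
        for c, s, d in zip(spec.stage_channels, spec.stage_strides, spec.stage_dilations):
            self.stages.append(_Stage(prev, c, s, d, rng))
            prev = c

    def forward(self, x):
        for conv in self.stem:
            x = conv(x).relu()
        taps = []
        for stage in self.stages:
            x = stage(x)
            taps.append(x)
        return taps


class ASPP(Module):
    def __init__(self, in_ch: int, cfg: ASPPConfig, rng):
        bc = cfg.branch_channels
        self.cfg = cfg
        self.proj1x1 = Conv2d(in_ch, bc, 1, rng=rng)
        if cfg.separable:
            self.branches = [SeparableConv2d(in_ch, bc, dilation=r, rng=rng)
                             for r in cfg.dilation_rates]
        else:
            self.branches = [Conv2d(in_ch, bc, 3, padding=r, dilation=r, rng=rng)
                             for r in cfg.dilation_rates]
        self.image_pool_conv = Conv2d(in_ch, bc, 1, rng=rng) if cfg.image_pooling else None
        n_branch = 1 + len(cfg.dilation_rates) + (1 if cfg.image_pooling else 0)
        self.project = Conv2d(n_branch * bc, bc, 1, rng=rng)

    def forward(self, x):
        outs = [self.proj1x1(x).relu()]
        outs += [b(x).relu() for b in self.branches]
        if self.image_pool_conv is not None:
            pooled = self.image_pool_conv(x.mean(axis=(2, 3), keepdims=True)).relu()
            h, w = x.shape[2], x.shape[3]
            outs.append(pooled * Tensor(np.ones((1, 1, h, w), dtype=np.float32)))
        return self.project(nn.concat(outs, axis=1)).relu()


class PeMNet(Module):
    """The assembled segmentation model (baseline when ``gcam`` is None)."""

    def __init__(self, cfg: PeMNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        # independent streams per block keep shared weights identical
        # between a GCAM model and its attention-free baseline at equal seed
        bb_rng, gcam_rng, aspp_rng, dec_rng = rng.spawn(4)
        self.cfg = cfg
        self.backbone = Backbone(cfg.backbone, bb_rng)
        self.gcam = GCAMChain(cfg.gcam, gcam_rng) if cfg.gcam is not None else None
        self.aspp = ASPP(cfg.backbone.stage_channels[-1], cfg.aspp, aspp_rng)
        bc = cfg.aspp.branch_channels
        self.low_proj = Conv2d(cfg.backbone.stage_channels[cfg.low_level_tap],
                               cfg.low_level_channels, 1, rng=dec_rng)
        self.fuse = Conv2d(bc + cfg.low_level_channels, cfg.decoder_channels, 3,
                           padding=1, rng=dec_rng)
        self.head = Conv2d(cfg.decoder_channels, cfg.num_classes, 1,
                           rng=dec_rng, init="zeros")
        bb = cfg.backbone
        low_stride = bb.stem_downsample * int(np.prod(bb.stage_strides[:cfg.low_level_tap + 1]))
        self._up1 = bb.output_stride // low_stride
        self._up2 = low_stride

    def forward(self, x, force_identity_attention: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        taps = self.backbone(x)
        if self.gcam is not None:
            feats = self.gcam(taps[self.cfg.tap_start:],
                              force_identity=force_identity_attention)
        else:
            feats = taps[-1]
        y = self.aspp(feats)
        if self._up1 > 1:
            y = upsample_bilinear(y, self._up1)
        low = self.low_proj(taps[self.cfg.low_level_tap]).relu()
        y = self.fuse(nn.concat([y, low], axis=1)).relu()
        logits = self.head(y)
        return upsample_bilinear(logits, self._up2)


def build_model(cfg: PeMNetConfig, seed: int = 0) -> PeMNet:
    """Deterministically initialised model; the parameter count of a GCAM
    model exceeds its attention-free twin by exactly ``budget_chain``."""
    return PeMNet(cfg, seed=seed)


def save_model(model: PeMNet, path):
    """Checkpoint: weights as an npz archive with the config embedded as JSON."""
    import json

    from . import config as _config

    sd = {f"param/{k}": v for k, v in model.state_dict().items()}
    sd["config_json"] = np.frombuffer(
        json.dumps(_config.to_dict(model.cfg), sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **sd)


def load_model(path) -> PeMNet:
    import json

    from . import config as _config

    with np.load(path) as data:
        cfg = _config.model_config_from_dict(
            json.loads(bytes(data["config_json"]).decode()))
        model = PeMNet(cfg, seed=0)
        model.load_state_dict({k[len("param/"):]: data[k]
                               for k in data.files if k.startswith("param/")})
    return model


def _check_input(model: PeMNet, image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    os_ = model.cfg.backbone.output_stride
    if arr.shape[2] % os_ or arr.shape[3] % os_:
        raise ValueError(
            f"input {arr.shape[2]}x{arr.shape[3]} is not divisible by the "
            f"output stride {os_}; pad the image to a multiple first")
    return arr


def predict_proba(model: PeMNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities, shape (K, H, W)."""
    arr = _check_input(model, image)
    logits = model.forward(arr).data[0]
    z = logits - logits.max(axis=0, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=0, keepdims=True)


def predict_mask(model: PeMNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax mask; ties resolve to class 0 (non-pectoral)."""
    arr = _check_input(model, image)
    logits = model.forward(arr).data[0]
    # argmax takes the first maximal index, so exact ties fall to class 0
    return logits.argmax(axis=0).astype(np.uint8)
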