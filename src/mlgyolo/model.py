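"""Detector assembly: baseline YOLOv8n and its lightweight variants.

The baseline is the standard YOLOv8n (C2f backbone, FPN+PAN neck, decoupled
anchor-free head). Three orthogonal modifications can be combined:

* ``mobilevit`` — replace the backbone with a MobileViT-style stem
  (MV2 inverted residuals + hybrid transformer blocks) tapping P3/P4/P5,
  with a correspondingly narrower neck;
* ``lsk`` — insert one large-selective-kernel attention block after the
  P3-scale processing layer of the neck (the position that works best for
  small fruit);
* ``gsconv`` — replace the two dense stride-2 convolutions in the PAN
  downsampling path with GSConv.

Parameter counts of the calibrated configurations (single class):

==============================  ==========
yolov8n                          3,011,043
yolov8n + lsk                    3,022,377
yolov8n + gsconv                 2,921,283
yolov8n + lsk + gsconv           2,932,617
mobilevit backbone only          1,181,111
full model (all three)           1,173,429
==============================  ==========
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .blocks import (C2f, Detect, GSConv, GSConvConfig, LSKBlock, LSKConfig,
                     MV2, MobileViTBlock, MobileViTConfig, SPPF)
from .layers import ConvBnAct, Identity, Module, Sequential, set_seed
from .tensor import Tensor, no_grad

__all__ = ["ModelConfig", "ParameterReport", "build_model", "count_parameters",
           "count_flops", "summarize", "VARIANTS", "Detector"]

VARIANTS = {
    "yolov8n": (),
    "yolov8n-lsk": ("lsk",),
    "yolov8n-gsconv": ("gsconv",),
    "yolov8n-lsk-gsconv": ("lsk", "gsconv"),
    "mobilevit": ("mobilevit",),
    "mobilevit-lsk": ("mobilevit", "lsk"),
    "mobilevit-gsconv": ("mobilevit", "gsconv"),
    "mlg-yolo": ("mobilevit", "lsk", "gsconv"),
}


@dataclass
class ModelConfig:
    """Variant flags plus the canonical calibrated widths."""
    variant: str = "mlg-yolo"
    nc: int = 1
    imgsz: int = 640
    lsk_position: str = "P3"            # insertion point of the attention block
    # standard YOLOv8n widths
    yolo_channels: tuple = (16, 32, 64, 128, 256)
    yolo_neck: tuple = (64, 128, 256)
    # MobileViT backbone: stem, stage1, stage2, P3, P4, P5 channels
    mvit_channels: tuple = (16, 16, 24, 36, 60, 72)
    mvit_dims: tuple = (64, 76, 80)     # transformer widths at P3/P4/P5
    mvit_depths: tuple = (2, 3, 3)
    mvit_expand: int = 2
    mvit_neck: tuple = (40, 40, 96)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}")
        if self.nc < 1:
            raise ValueError("nc must be >= 1")
        if self.lsk_position not in ("P3", "P4", "P5"):
            raise ValueError("lsk_position must be P3, P4 or P5")

    @property
    def flags(self) -> frozenset:
        return frozenset(VARIANTS[self.variant])

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        for k in ("yolo_channels", "yolo_neck", "mvit_channels", "mvit_dims",
                  "mvit_depths", "mvit_neck"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ParameterReport:
    variant: str
    nc: int
    imgsz: int
    parameters: int
    gflops: float
    size_mb_fp32: float
    size_mb_fp16: float


class YoloBackbone(Module):
    """Standard YOLOv8n backbone (depth 0.33 / width 0.25)."""

    def __init__(self, ch=(16, 32, 64, 128, 256)):
        super().__init__()
        c1, c2, c3, c4, c5 = ch
        self.out_channels = (c3, c4, c5)
        self.stem = ConvBnAct(3, c1, 3, stride=2)
        self.stage2 = Sequential(ConvBnAct(c1, c2, 3, stride=2), C2f(c2, c2, 1, shortcut=True))
        self.stage3 = Sequential(ConvBnAct(c2, c3, 3, stride=2), C2f(c3, c3, 2, shortcut=True))
        self.stage4 = Sequential(ConvBnAct(c3, c4, 3, stride=2), C2f(c4, c4, 2, shortcut=True))
        self.stage5 = Sequential(ConvBnAct(c4, c5, 3, stride=2), C2f(c5, c5, 1, shortcut=True),
                                 SPPF(c5, c5))

    def forward(self, x):
        x = self.stage2(self.stem(x))
        p3 = self.stage3(x)
        p4 = self.stage4(p3)
        p5 = self.stage5(p4)
        return p3, p4, p5

    def flops(self, h, w):
        f, hw = 0.0, (h, w)
        for m in (self.stem, self.stage2, self.stage3, self.stage4, self.stage5):
            f += m.flops(*hw)
            hw = m.out_hw(*hw)
        return f


class MobileViTBackbone(Module):
    """MobileViT-style backbone: stem + MV2 stages with hybrid blocks at P3-P5."""

    def __init__(self, ch=(16, 16, 24, 36, 60, 72), dims=(64, 76, 80),
                 depths=(2, 3, 3), expand=2):
        super().__init__()
        c0, c1, c2, c3, c4, c5 = ch
        self.out_channels = (c3, c4, c5)
        self.stem = ConvBnAct(3, c0, 3, stride=2)
        self.stage1 = MV2(c0, c1, 1, expand)
        self.stage2 = Sequential(MV2(c1, c2, 2, expand), MV2(c2, c2, 1, expand))
        self.stage3 = Sequential(
            MV2(c2, c3, 2, expand),
            MobileViTBlock(c3, MobileViTConfig(dim=dims[0], depth=depths[0])))
        self.stage4 = Sequential(
            MV2(c3, c4, 2, expand),
            MobileViTBlock(c4, MobileViTConfig(dim=dims[1], depth=depths[1])))
        self.stage5 = Sequential(
            MV2(c4, c5, 2, expand),
            MobileViTBlock(c5, MobileViTConfig(dim=dims[2], depth=depths[2])),
            SPPF(c5, c5))

    def forward(self, x):
        x = self.stage2(self.stage1(self.stem(x)))
        p3 = self.stage3(x)
        p4 = self.stage4(p3)
        p5 = self.stage5(p4)
        return p3, p4, p5

    def flops(self, h, w):
        f, hw = 0.0, (h, w)
        for m in (self.stem, self.stage1, self.stage2, self.stage3, self.stage4, self.stage5):
            f += m.flops(*hw)
            hw = m.out_hw(*hw)
        return f


class Neck(Module):
    """FPN top-down + PAN bottom-up feature aggregation."""

    def __init__(self, in_ch, out_ch, use_gsconv=False, lsk_position=None):
        super().__init__()
        c3, c4, c5 = in_ch
        n3, n4, n5 = out_ch
        self.out_channels = (n3, n4, n5)
        self.td4 = C2f(c5 + c4, n4, 1)
        self.td3 = C2f(n4 + c3, n3, 1)
        if use_gsconv:
            self.down3 = GSConv(GSConvConfig(n3, n3, 3, stride=2))
            self.down4 = GSConv(GSConvConfig(n4, n4, 3, stride=2))
        else:
            self.down3 = ConvBnAct(n3, n3, 3, stride=2)
            self.down4 = ConvBnAct(n4, n4, 3, stride=2)
        self.bu4 = C2f(n3 + n4, n4, 1)
        self.bu5 = C2f(n4 + c5, n5, 1)
        self.lsk3 = self.lsk4 = self.lsk5 = None
        if lsk_position == "P3":
            self.lsk3 = LSKBlock(LSKConfig(n3))
        elif lsk_position == "P4":
            self.lsk4 = LSKBlock(LSKConfig(n4))
        elif lsk_position == "P5":
            self.lsk5 = LSKBlock(LSKConfig(n5))

    def forward(self, p3, p4, p5):
        m4 = self.td4(Tensor.concat([p5.upsample_nearest(2), p4], axis=1))
        t3 = self.td3(Tensor.concat([m4.upsample_nearest(2), p3], axis=1))
        if self.lsk3 is not None:
            t3 = self.lsk3(t3)
        t4 = self.bu4(Tensor.concat([self.down3(t3), m4], axis=1))
        if self.lsk4 is not None:
            t4 = self.lsk4(t4)
        t5 = self.bu5(Tensor.concat([self.down4(t4), p5], axis=1))
        if self.lsk5 is not None:
            t5 = self.lsk5(t5)
        return t3, t4, t5

    def flops(self, hw3, hw4, hw5):
        f = self.td4.flops(*hw4) + self.td3.flops(*hw3)
        for lsk, hw in ((self.lsk3, hw3), (self.lsk4, hw4), (self.lsk5, hw5)):
            if lsk is not None:
                f += lsk.flops(*hw)
        f += self.down3.flops(*hw3) + self.bu4.flops(*hw4)
        f += self.down4.flops(*hw4) + self.bu5.flops(*hw5)
        return f


class Detector(Module):
    """Backbone + neck + anchor-free head; raw multi-scale outputs."""

    strides = (8, 16, 32)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        set_seed(cfg.seed)
        self.cfg = cfg
        flags = cfg.flags
        if "mobilevit" in flags:
            self.backbone = MobileViTBackbone(cfg.mvit_channels, cfg.mvit_dims,
                                              cfg.mvit_depths, cfg.mvit_expand)
            neck_ch = cfg.mvit_neck
        else:
            self.backbone = YoloBackbone(cfg.yolo_channels)
            neck_ch = cfg.yolo_neck
        self.neck = Neck(self.backbone.out_channels, neck_ch,
                         use_gsconv="gsconv" in flags,
                         lsk_position=cfg.lsk_position if "lsk" in flags else None)
        self.head = Detect(cfg.nc, neck_ch)

    def forward(self, x: Tensor):
        p3, p4, p5 = self.backbone(x)
        t3, t4, t5 = self.neck(p3, p4, p5)
        return self.head([t3, t4, t5])

    def flops(self, h: int, w: int) -> float:
        if h % 32 or w % 32:
            raise ValueError("input size must be divisible by 32")
        hw = [(h // s, w // s) for s in self.strides]
        return self.backbone.flops(h, w) + self.neck.flops(*hw) + self.head.flops(hw)


def build_model(cfg: ModelConfig | str | None = None, **kw) -> Detector:
    """Build a detector from a config, a variant tag, or keyword overrides."""
    if cfg is None:
        cfg = ModelConfig(**kw)
    elif isinstance(cfg, str):
        cfg = ModelConfig(variant=cfg, **kw)
    return Detector(cfg)


def count_parameters(model: Module) -> int:
    """Total parameter elements (trainable weights plus frozen projections)."""
    return model.num_params()


def count_flops(model: Detector, imgsz: int | tuple[int, int] = 640) -> float:
    """Forward-pass FLOPs in units of 1e9, 2 ops per multiply-accumulate."""
    h, w = (imgsz, imgsz) if isinstance(imgsz, int) else imgsz
    return model.flops(h, w) / 1e9


def summarize(cfg: ModelConfig | str, imgsz: int | None = None) -> ParameterReport:
    if isinstance(cfg, str):
        cfg = ModelConfig(variant=cfg)
    model = build_model(cfg)
    imgsz = imgsz or cfg.imgsz
    n = count_parameters(model)
    return ParameterReport(
        variant=cfg.variant, nc=cfg.nc, imgsz=imgsz,
        parameters=n, gflops=round(count_flops(model, imgsz), 2),
        size_mb_fp32=round(n * 4 / 1e6, 2), size_mb_fp16=round(n * 2 / 1e6, 2))


def save_checkpoint(path, model: Detector):
    """Weights + the config that rebuilds them, in a single .npz."""
    state = model.state_dict()
    cfg_yaml = model.cfg.to_yaml()
    np.savez(path, __config__=np.frombuffer(cfg_yaml.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> Detector:
    data = np.load(path)
    cfg = ModelConfig.from_yaml(bytes(data["__config__"]).decode())
    model = Detector(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
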