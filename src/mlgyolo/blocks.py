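"""Architectural building blocks.

Three families live here:

* the YOLOv8 bricks (``C2f``, ``SPPF``, ``Detect``) that make up the
  baseline single-stage detector;
* the hybrid convolution-transformer ``MobileViTBlock`` (with its patch
  ``mobilevit_unfold``/``mobilevit_fold`` pair) and the ``MV2`` inverted
  residual used to rebuild the backbone;
* the ``LSKBlock`` large-selective-kernel spatial attention and the
  ``GSConv`` half-dense/half-depthwise convolution with channel shuffle
  used to lighten the neck.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm2d, Conv2d, ConvBnAct, LayerNorm, Linear,
                     Module, MultiHeadSelfAttention, Sequential)
from .tensor import Tensor

__all__ = [
    "MobileViTConfig", "LSKConfig", "GSConvConfig",
    "mobilevit_unfold", "mobilevit_fold", "channel_shuffle",
    "MobileViTBlock", "MV2", "LSKBlock", "GSConv",
    "Bottleneck", "C2f", "SPPF", "Detect", "DFL_BINS",
]

DFL_BINS = 16  # distribution-focal-loss bins per box side


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------
@dataclass
class MobileViTConfig:
    """Hybrid block geometry.

    ``patch_h``/``patch_w`` must not exceed the local kernel ``n`` and the
    feature map must tile exactly into patches. ``dim`` is the expanded
    transformer width d (> input channels).
    """
    dim: int
    depth: int
    local_kernel: int = 3
    patch_h: int = 2
    patch_w: int = 2
    heads: int = 4
    mlp_ratio: int = 2

    def __post_init__(self):
        if self.patch_h > self.local_kernel or self.patch_w > self.local_kernel:
            raise ValueError("patch size must be <= local kernel size")
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")


@dataclass
class LSKConfig:
    """Large-selective-kernel decomposition.

    ``decomposition`` lists (kernel, dilation) per stage; the effective
    receptive field must strictly grow along it. Default is the reference
    decomposition: a 5x5 depthwise conv followed by a 7x7 depthwise conv
    with dilation 3 (effective 23x23).
    """
    channels: int
    decomposition: tuple[tuple[int, int], ...] = ((5, 1), (7, 3))
    squeeze_kernel: int = 7

    def __post_init__(self):
        eff = 0
        for k, d in self.decomposition:
            eff_k = d * (k - 1) + 1      # effective kernel of this stage
            if eff_k <= eff:
                raise ValueError("receptive field must strictly increase "
                                 "along the decomposition")
            eff = eff_k
        if self.channels % 2:
            raise ValueError("channel count must be even (C/2 projections)")


@dataclass
class GSConvConfig:
    cin: int
    cout: int
    kernel: int = 3
    stride: int = 1
    dw_kernel: int = 5

    def __post_init__(self):
        if self.cout % 2:
            raise ValueError("GSConv output channels must be even")


# ---------------------------------------------------------------------------
# patch unfold / fold
# ---------------------------------------------------------------------------
def mobilevit_unfold(x: Tensor, patch_h: int, patch_w: int) -> Tensor:
    """(B, d, H, W) -> (B, P, N, d) flattened non-overlapping patches.

    P = patch_h * patch_w intra-patch positions (row-major within a patch),
    N = H*W/P patches (row-major over the patch grid). Requires H divisible
    by patch_h and W by patch_w; no silent padding.
    """
    b, d, h, w = x.shape
    if h % patch_h or w % patch_w:
        raise ValueError(
            f"feature map {h}x{w} does not tile into {patch_h}x{patch_w} patches")
    nh, nw = h // patch_h, w // patch_w
    # (b,d,nh,ph,nw,pw) -> (b, ph*pw, nh*nw, d)
    x = x.reshape(b, d, nh, patch_h, nw, patch_w)
    x = x.transpose(0, 3, 5, 2, 4, 1)
    return x.reshape(b, patch_h * patch_w, nh * nw, d)


def mobilevit_fold(xg: Tensor, patch_h: int, patch_w: int, h: int, w: int) -> Tensor:
    """Exact inverse of :func:`mobilevit_unfold`: (B,P,N,d) -> (B,d,H,W)."""
    b, p, n, d = xg.shape
    if p != patch_h * patch_w or n * p != h * w:
        raise ValueError(f"cannot fold {p}x{n} patches into {h}x{w}")
    nh, nw = h // patch_h, w // patch_w
    x = xg.reshape(b, patch_h, patch_w, nh, nw, d)
    x = x.transpose(0, 5, 3, 1, 4, 2)
    return x.reshape(b, d, h, w)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channels across ``groups`` evenly.

    Output channel ``i`` holds input channel ``(i % groups) * (C//groups)
    + i // groups`` — the standard group-interleave permutation. Bijective;
    per-pixel value multisets are preserved.
    """
    b, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels ({c}) not divisible by groups ({groups})")
    return (x.reshape(b, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(b, c, h, w))


# ---------------------------------------------------------------------------
# MobileViT
# ---------------------------------------------------------------------------
class _TransformerLayer(Module):
    """Pre-norm encoder layer: LN -> MHSA -> add, LN -> MLP -> add."""

    def __init__(self, d: int, heads: int, mlp_ratio: int):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, mlp_ratio * d)
        self.fc2 = Linear(mlp_ratio * d, d)
        self.d, self.mlp_ratio = d, mlp_ratio

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).silu())

    def flops_tokens(self, n):
        return (self.ln1.flops_tokens(n) + self.attn.flops_tokens(n)
                + self.ln2.flops_tokens(n) + self.fc1.flops_tokens(n)
                + 2.0 * self.mlp_ratio * self.d * n + self.fc2.flops_tokens(n))


class MobileViTBlock(Module):
    """Local conv encoding -> patch transformer -> fold -> fuse with input.

    Input and output are (B, C, H, W) with identical shapes. The expanded
    width ``cfg.dim`` must exceed C.
    """

    def __init__(self, c: int, cfg: MobileViTConfig):
        super().__init__()
        if cfg.dim <= c:
            raise ValueError(f"expanded dim d={cfg.dim} must exceed input channels C={c}")
        self.c, self.cfg = c, cfg
        n = cfg.local_kernel
        self.conv_local = ConvBnAct(c, c, n)
        self.conv_expand = Conv2d(c, cfg.dim, 1, bias=False)
        self.transformer = Sequential(
            *[_TransformerLayer(cfg.dim, cfg.heads, cfg.mlp_ratio) for _ in range(cfg.depth)])
        self.ln_out = LayerNorm(cfg.dim)
        self.conv_project = ConvBnAct(cfg.dim, c, 1)
        self.conv_fuse = ConvBnAct(2 * c, c, n)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        y = self.conv_expand(self.conv_local(x))
        y = mobilevit_unfold(y, self.cfg.patch_h, self.cfg.patch_w)  # (B,P,N,d)
        bp, p, n, d = y.shape
        y = y.reshape(b * p, n, d)          # per-position sequences across patches
        y = self.ln_out(self.transformer(y))
        y = y.reshape(b, p, n, d)
        y = mobilevit_fold(y, self.cfg.patch_h, self.cfg.patch_w, h, w)
        y = self.conv_project(y)
        return self.conv_fuse(Tensor.concat([x, y], axis=1))

    def flops(self, h, w):
        n_tok = h * w
        f = self.conv_local.flops(h, w)
        f += 2.0 * self.c * self.cfg.dim * n_tok
        for layer in self.transformer:
            f += layer.flops_tokens(n_tok)
        f += self.ln_out.flops_tokens(n_tok)
        f += self.conv_project.flops(h, w)
        f += self.conv_fuse.flops(h, w)
        return f


class MV2(Module):
    """MobileNetV2 inverted residual (expand -> depthwise -> project)."""

    def __init__(self, cin: int, cout: int, stride: int = 1, expand: int = 2):
        super().__init__()
        h = expand * cin
        self.use_res = stride == 1 and cin == cout
        layers = []
        if expand != 1:
            layers.append(ConvBnAct(cin, h, 1))
        layers.append(ConvBnAct(h, h, 3, stride=stride, groups=h))
        layers.append(ConvBnAct(h, cout, 1, act=None))
        self.block = Sequential(*layers)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_res else y

    def flops(self, h, w):
        return self.block.flops(h, w)

    def out_hw(self, h, w):
        return self.block.out_hw(h, w)


# ---------------------------------------------------------------------------
# LSK attention
# ---------------------------------------------------------------------------
class LSKBlock(Module):
    """Large-selective-kernel spatial attention.

    Contexts from a growing depthwise-kernel decomposition are projected to
    C/2, pooled across channels (mean and max per pixel), turned into one
    sigmoid mask per decomposition stage by a small conv, recombined under
    those masks, fused by a 1x1 conv, and applied multiplicatively to the
    input. Output shape equals input shape.
    """

    def __init__(self, cfg: LSKConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        (k0, d0), (k1, d1) = cfg.decomposition
        self.conv0 = Conv2d(c, c, k0, dilation=d0, groups=c)
        self.conv_spatial = Conv2d(c, c, k1, dilation=d1, groups=c)
        self.proj1 = Conv2d(c, c // 2, 1)
        self.proj2 = Conv2d(c, c // 2, 1)
        self.conv_squeeze = Conv2d(2, 2, cfg.squeeze_kernel)
        self.conv_fuse = Conv2d(c // 2, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        ctx1 = self.conv0(x)
        ctx2 = self.conv_spatial(ctx1)
        a1 = self.proj1(ctx1)
        a2 = self.proj2(ctx2)
        stacked = Tensor.concat([a1, a2], axis=1)
        avg_pool = stacked.mean(axis=1, keepdims=True)      # channelwise pooling
        # max over channels: use numpy argmax trick via maximum-reduce composite
        max_pool = _channel_max(stacked)
        masks = self.conv_squeeze(Tensor.concat([avg_pool, max_pool], axis=1)).sigmoid()
        sel = a1 * masks[:, 0:1] + a2 * masks[:, 1:2]
        attention = self.conv_fuse(sel)
        return x * attention

    def masks(self, x: Tensor) -> np.ndarray:
        """The per-stage spatial selection masks (values in [0, 1])."""
        ctx1 = self.conv0(x)
        ctx2 = self.conv_spatial(ctx1)
        stacked = Tensor.concat([self.proj1(ctx1), self.proj2(ctx2)], axis=1)
        agg = Tensor.concat([stacked.mean(axis=1, keepdims=True), _channel_max(stacked)], axis=1)
        return self.conv_squeeze(agg).sigmoid().data

    def flops(self, h, w):
        c = self.cfg.channels
        f = self.conv0.flops(h, w) + self.conv_spatial.flops(h, w)
        f += self.proj1.flops(h, w) + self.proj2.flops(h, w)
        f += self.conv_squeeze.flops(h, w) + 2.0 * 2 * h * w  # + sigmoid
        f += self.conv_fuse.flops(h, w)
        return f


def _channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis with gradient to the argmax entries."""
    data = x.data
    arg = data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(data, arg, axis=1)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(data)
            np.put_along_axis(full, arg, g, axis=1)
            x._accum(full)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# GSConv
# ---------------------------------------------------------------------------
class GSConv(Module):
    """Half dense / half depthwise convolution with channel shuffle.

    A dense conv maps C1 -> C2/2; a depthwise conv refines that half; the
    two halves are concatenated and uniformly interleaved so dense
    information diffuses into every output channel.
    """

    def __init__(self, cfg: GSConvConfig):
        super().__init__()
        self.cfg = cfg
        half = cfg.cout // 2
        self.dense = ConvBnAct(cfg.cin, half, cfg.kernel, stride=cfg.stride)
        self.depthwise = ConvBnAct(half, half, cfg.dw_kernel, groups=half)

    def forward(self, x: Tensor) -> Tensor:
        a = self.dense(x)
        b = self.depthwise(a)
        return channel_shuffle(Tensor.concat([a, b], axis=1), 2)

    def out_hw(self, h, w):
        return self.dense.out_hw(h, w)

    def flops(self, h, w):
        ho, wo = self.dense.out_hw(h, w)
        return self.dense.flops(h, w) + self.depthwise.flops(ho, wo)


# ---------------------------------------------------------------------------
# YOLOv8 bricks
# ---------------------------------------------------------------------------
class Bottleneck(Module):
    def __init__(self, cin, cout, shortcut=True):
        super().__init__()
        self.cv1 = ConvBnAct(cin, cout, 3)
        self.cv2 = ConvBnAct(cout, cout, 3)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def flops(self, h, w):
        return self.cv1.flops(h, w) + self.cv2.flops(h, w)


class C2f(Module):
    """Cross-stage partial block with n bottlenecks (YOLOv8 backbone/neck unit)."""

    def __init__(self, cin, cout, n=1, shortcut=False):
        super().__init__()
        self.c = cout // 2
        self.n = n
        self.cv1 = ConvBnAct(cin, 2 * self.c, 1)
        self.cv2 = ConvBnAct((2 + n) * self.c, cout, 1)
        self.m = Sequential(*[Bottleneck(self.c, self.c, shortcut) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        parts = [a, b]
        for bot in self.m:
            parts.append(bot(parts[-1]))
        return self.cv2(Tensor.concat(parts, axis=1))

    def flops(self, h, w):
        f = self.cv1.flops(h, w) + self.cv2.flops(h, w)
        for bot in self.m:
            f += bot.flops(h, w)
        return f


class SPPF(Module):
    """Spatial pyramid pooling (fast): three cascaded 5x5 max pools."""

    def __init__(self, cin, cout, k=5):
        super().__init__()
        c = cin // 2
        self.k = k
        self.c = c
        self.cv1 = ConvBnAct(cin, c, 1)
        self.cv2 = ConvBnAct(4 * c, cout, 1)

    def forward(self, x):
        x = self.cv1(x)
        p1 = x.maxpool2d(self.k, stride=1, padding=self.k // 2)
        p2 = p1.maxpool2d(self.k, stride=1, padding=self.k // 2)
        p3 = p2.maxpool2d(self.k, stride=1, padding=self.k // 2)
        return self.cv2(Tensor.concat([x, p1, p2, p3], axis=1))

    def flops(self, h, w):
        return (self.cv1.flops(h, w) + self.cv2.flops(h, w)
                + 3.0 * self.k * self.k * self.c * h * w)


class Detect(Module):
    """Decoupled anchor-free head at three scales.

    Per scale a box branch emits 4*DFL_BINS distribution logits and a class
    branch emits nc logits per cell. The frozen DFL projection (expectation
    over bins) is part of the module so parameter reports match the usual
    whole-model accounting.
    """

    def __init__(self, nc: int, ch: tuple[int, int, int], strides=(8, 16, 32)):
        super().__init__()
        self.nc = nc
        self.ch = tuple(ch)
        self.strides = tuple(strides)
        self.reg_max = DFL_BINS
        c2 = max(16, ch[0] // 4, 4 * self.reg_max)
        c3 = max(ch[0], min(nc, 100))
        self.c2, self.c3 = c2, c3
        for i, c in enumerate(ch):
            box = Sequential(ConvBnAct(c, c2, 3), ConvBnAct(c2, c2, 3),
                             Conv2d(c2, 4 * self.reg_max, 1, bias=True))
            cls = Sequential(ConvBnAct(c, c3, 3), ConvBnAct(c3, c3, 3),
                             Conv2d(c3, nc, 1, bias=True))
            # stable start: boxes near small distances, classes near p~=0.01
            box[-1].bias.data[:] = 1.0
            cls[-1].bias.data[:] = -4.6
            setattr(self, f"box{i}", box)
            setattr(self, f"cls{i}", cls)
        self.dfl = Conv2d(self.reg_max, 1, 1, bias=False, trainable=False)
        self.dfl.weight.data = np.arange(self.reg_max, dtype=np.float32).reshape(1, -1, 1, 1)

    def branches(self, i):
        return getattr(self, f"box{i}"), getattr(self, f"cls{i}")

    def forward(self, feats: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        out = []
        for i, f in enumerate(feats):
            box, cls = self.branches(i)
            out.append((box(f), cls(f)))
        return out

    def flops(self, hw_per_scale):
        f = 0.0
        anchors = 0
        for i, (h, w) in enumerate(hw_per_scale):
            box, cls = self.branches(i)
            f += box.flops(h, w) + cls.flops(h, w)
            anchors += h * w
        f += 2.0 * self.reg_max * 4 * anchors  # DFL expectation
        return f
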