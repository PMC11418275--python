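"""Neural-network layers with built-in parameter and FLOP accounting.

Every layer reports ``num_params()`` (all parameter elements, trainable or
frozen) and ``flops(h, w)`` — the floating-point operations of one forward
pass on an ``h x w`` input, under the layer-op convention: 2 ops per
multiply-accumulate in convolutions and linear maps, 1 per bias add, 4 per
element for an affine batch norm, 2 per element for an activation, ``k^2``
per output element for max pooling, 7 per element for layer norm. Attention
tensor products and softmax are not attributed FLOPs, matching the counters
commonly used to profile detection models.
"""
from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvBnAct", "BatchNorm2d", "Linear",
    "LayerNorm", "MultiHeadSelfAttention", "Identity", "set_seed",
]

_rng = np.random.default_rng(0)


def set_seed(seed: int):
    """Seed weight initialisation globally."""
    global _rng
    _rng = np.random.default_rng(seed)


class Module:
    """Minimal torch-like module: parameter registry, train/eval flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            out.extend(m._params.values())
        return out

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            key = prefix + name
            src = np.asarray(state[key], dtype=np.float32)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {p.data.shape}")
            p.data = src.copy()
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def flops(self, h: int, w: int) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return h, w


class Identity(Module):
    def forward(self, x):
        return x

    def flops(self, h, w):
        return 0.0


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            self._modules[str(i)] = l

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def flops(self, h, w):
        total = 0.0
        for l in self.layers:
            total += l.flops(h, w)
            h, w = l.out_hw(h, w)
        return total

    def out_hw(self, h, w):
        for l in self.layers:
            h, w = l.out_hw(h, w)
        return h, w


def _kaiming(shape, fan_in):
    bound = math.sqrt(2.0 / fan_in)
    return (_rng.standard_normal(shape) * bound).astype(np.float32)


class Conv2d(Module):
    """Bare convolution (optionally frozen weights, e.g. a DFL projection)."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, dilation=1,
                 groups=1, bias=True, trainable=True):
        super().__init__()
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = cin // groups * k * k
        self.weight = self.register(
            "weight", Tensor(_kaiming((cout, cin // groups, k, k), fan_in),
                             requires_grad=trainable))
        self.bias = None
        if bias:
            self.bias = self.register(
                "bias", Tensor(np.zeros(cout, dtype=np.float32), requires_grad=trainable))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation, groups=self.groups)

    def out_hw(self, h, w):
        ho = (h + 2 * self.padding - self.dilation * (self.k - 1) - 1) // self.stride + 1
        wo = (w + 2 * self.padding - self.dilation * (self.k - 1) - 1) // self.stride + 1
        return ho, wo

    def flops(self, h, w):
        ho, wo = self.out_hw(h, w)
        macs = self.k * self.k * self.cin // self.groups * self.cout * ho * wo
        f = 2.0 * macs
        if self.bias is not None:
            f += self.cout * ho * wo
        return f


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        # YOLO-family convention: eps 1e-3, EMA momentum 0.03
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = self.register("weight", Tensor(np.ones(c, dtype=np.float32), requires_grad=True))
        self.bias = self.register("bias", Tensor(np.zeros(c, dtype=np.float32), requires_grad=True))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.size / self.c
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, self.c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, self.c, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        return xhat * w + b

    def flops(self, h, w):
        return 4.0 * self.c * h * w


class _Act(Module):
    def __init__(self, kind="silu"):
        super().__init__()
        self.kind = kind

    def forward(self, x):
        return getattr(x, self.kind)()

    def flops(self, h, w):
        return 0.0  # counted by the owning ConvBnAct


class ConvBnAct(Module):
    """Conv + BatchNorm + activation, the standard YOLO building brick."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, dilation=1,
                 groups=1, act="silu"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, dilation, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act
        self.cout = cout

    def forward(self, x):
        x = self.bn(self.conv(x))
        return getattr(x, self.act)() if self.act else x

    def out_hw(self, h, w):
        return self.conv.out_hw(h, w)

    def flops(self, h, w):
        ho, wo = self.conv.out_hw(h, w)
        f = self.conv.flops(h, w) + self.bn.flops(ho, wo)
        if self.act:
            f += 2.0 * self.cout * ho * wo
        return f


class Linear(Module):
    def __init__(self, cin, cout, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        bound = math.sqrt(1.0 / cin)
        self.weight = self.register(
            "weight", Tensor((_rng.uniform(-bound, bound, (cin, cout))).astype(np.float32),
                             requires_grad=True))
        self.bias = None
        if bias:
            self.bias = self.register(
                "bias", Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def flops_tokens(self, n_tokens: int) -> float:
        f = 2.0 * self.cin * self.cout * n_tokens
        if self.bias is not None:
            f += self.cout * n_tokens
        return f


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.d, self.eps = d, eps
        self.weight = self.register("weight", Tensor(np.ones(d, dtype=np.float32), requires_grad=True))
        self.bias = self.register("bias", Tensor(np.zeros(d, dtype=np.float32), requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.weight + self.bias

    def flops_tokens(self, n_tokens):
        return 7.0 * self.d * n_tokens


class MultiHeadSelfAttention(Module):
    def __init__(self, d, heads):
        super().__init__()
        assert d % heads == 0, "embedding dim must be divisible by heads"
        self.d, self.heads = d, heads
        self.qkv = Linear(d, 3 * d)
        self.proj = Linear(d, d)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, N, d) -> (B, N, d)
        b, n, d = x.shape
        h = self.heads
        dh = d // h
        qkv = self.qkv(x).reshape(b, n, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (b, h, n, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)

    def flops_tokens(self, n_tokens):
        return self.qkv.flops_tokens(n_tokens) + self.proj.flops_tokens(n_tokens)
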