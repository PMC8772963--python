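"""Parameterised layers on top of the autodiff engine.

Modules hold :class:`~pemnet.nn.autodiff.Tensor` parameters and recurse
through attributes and lists for parameter discovery, state_dict export
and deterministic re-initialisation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


class Module:
    """Base class: parameter discovery, counting and (de)serialisation."""

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            yield from _walk(f"{prefix}{name}", val)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, sd: dict, strict: bool = True):
        own = dict(self.named_parameters())
        missing = set(own) - set(sd)
        extra = set(sd) - set(own)
        if strict and (missing or extra):
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            if name in sd:
                arr = np.asarray(sd[name], dtype=p.data.dtype)
                if arr.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{arr.shape} vs {p.data.shape}")
                p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _walk(name, val):
    if isinstance(val, Tensor):
        if val.requires_grad:
            yield name, val
    elif isinstance(val, Module):
        yield from val.named_parameters(f"{name}.")
    elif isinstance(val, (list, tuple)):
        for i, item in enumerate(val):
            yield from _walk(f"{name}.{i}", item)


def copy_shared_weights(src: Module, dst: Module):
    """Copy every parameter whose name and shape match from src to dst."""
    sd = src.state_dict()
    own = dict(dst.named_parameters())
    shared = {k: v for k, v in sd.items()
              if k in own and own[k].data.shape == v.shape}
    dst.load_state_dict(shared, strict=False)
    return sorted(shared)


class Conv2d(Module):
    """He-initialised 2-D convolution (NCHW, square kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 init: str = "he", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = (in_ch // groups) * kernel * kernel
        shape = (out_ch, in_ch // groups, kernel, kernel)
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        elif init == "zeros":
            w = np.zeros(shape)
        else:
            raise ValueError(f"unknown init '{init}'")
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, init: str = "he",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        elif init == "zeros":
            w = np.zeros((in_dim, out_dim))
        else:
            raise ValueError(f"unknown init '{init}'")
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class SeparableConv2d(Module):
    """Depthwise 3x3 (possibly dilated) followed by a pointwise projection."""

    def __init__(self, in_ch: int, out_ch: int, *, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        self.depthwise = Conv2d(in_ch, in_ch, 3, padding=dilation,
                                dilation=dilation, groups=in_ch, rng=rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x).relu())
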