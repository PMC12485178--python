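"""Neural-network modules built on the autodiff engine.

Follows the familiar Module/parameters/state_dict idiom so model code reads
like mainstream deep-learning code. All parameter initialization takes an
explicit ``numpy.random.Generator`` — there is no hidden global RNG.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield from m.named_parameters(f"{full}.{i}")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def param_digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, std: float | None = None):
        if std is None:
            w = he_normal(rng, (in_features, out_features), in_features)
        else:
            w = trunc_normal(rng, (in_features, out_features), std)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator,
                 stride: int = 1, pad=0, bias: bool = True):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = in_ch * kh * kw
        self.weight = Parameter(he_normal(rng, (out_ch, in_ch, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1, output_pad: int = 1, bias: bool = True):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.stride, self.pad, self.output_pad = stride, pad, output_pad

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride,
                                pad=self.pad, output_pad=self.output_pad)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.weight + self.bias


class GroupNorm(Module):
    """Batch-size-independent normalization over channel groups of an NCHW map."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = (xc * (var + self.eps) ** -0.5).reshape(n, c, h, w)
        wgt = self.weight.reshape(1, c, 1, 1)
        b = self.bias.reshape(1, c, 1, 1)
        return xhat * wgt + b


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()
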