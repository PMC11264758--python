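"""Neural-network layers, parameter containers and the Adam optimizer.

Thin, torch-like module system over :mod:`stcunet.autodiff`.  Layers take an
explicit ``numpy.random.Generator`` for initialization so every model build is
seedable, and an explicit ``dtype`` so gradient checks can run in float64.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data, dtype=None):
        super().__init__(data, requires_grad=True, dtype=dtype)


class Module:
    """Base class: tracks parameters, sub-modules, buffers and train mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- train / eval ------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer:" + name] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buf_owner: dict[str, tuple[Module, str]] = {}

        def walk(mod: Module, prefix: str = ""):
            for bname in mod._buffers:
                buf_owner[prefix + bname] = (mod, bname)
            for name, sub in mod._modules.items():
                walk(sub, prefix + name + ".")

        walk(self)
        for key, value in state.items():
            if key.startswith("buffer:"):
                owner, bname = buf_owner[key[len("buffer:"):]]
                if owner._buffers[bname].shape != value.shape:
                    raise ValueError(f"buffer {key} shape mismatch")
                owner._set_buffer(bname, value.copy())
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"parameter {key} shape mismatch")
                p.data = value.astype(p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = []
        for i, m in enumerate(mods):
            self._modules[str(i)] = m
            self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------

def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def trunc_normal(rng: np.random.Generator, shape, std: float, dtype) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(dtype)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear(Module):
    """y = x @ W + b with W of shape [in_features, out_features]."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "kaiming", dtype=np.float32):
        super().__init__()
        if init == "trunc_normal":
            w = trunc_normal(rng, (in_features, out_features), 0.02, dtype)
        else:
            w = kaiming_uniform(rng, (in_features, out_features), in_features, dtype)
        self.weight = Parameter(w)
        if bias:
            bound = 1.0 / np.sqrt(in_features)
            self.bias = Parameter(rng.uniform(-bound, bound, out_features).astype(dtype))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Stride-1 'same' convolution for odd kernels (padding = k // 2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in, dtype))
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Parameter(rng.uniform(-bound, bound, out_ch).astype(dtype))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.padding)


class ConvTranspose2d(Module):
    """Stride-2, kernel-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        fan_in = in_ch * 4
        self.weight = Parameter(kaiming_uniform(rng, (in_ch, out_ch, 2, 2), fan_in, dtype))
        bound = 1.0 / np.sqrt(fan_in)
        self.bias = Parameter(rng.uniform(-bound, bound, out_ch).astype(dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer(
                "running_mean",
                (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self._set_buffer(
                "running_var",
                (1 - m) * self.running_var + m * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=dtype))
        self.bias = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class Dropout(Module):
    """Inverted dropout; active only in train mode, seeded by its own rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool2x2(x)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-5, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
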