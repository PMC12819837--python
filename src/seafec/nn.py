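"""Layer/module system built on :mod:`seafec.tensor`.

Mirrors the conventional convolutional-network layer vocabulary
(Conv2d, BatchNorm2d, Linear, poolings, Sequential) with explicit
seeded initialisation: every parameterised layer draws its weights from
a caller-supplied :class:`numpy.random.Generator`, so a model built
twice from the same seed is bit-identical.

A multiply-accumulate (MAC) tally can be armed with :func:`tally_macs`;
while active, every convolution and linear layer adds its structural
MAC count (per batch element) to the tally during the forward pass.
"""

from __future__ import annotations

import contextlib
from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Identity",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "AvgPool2d",
    "AdaptiveAvgPool2d",
    "tally_macs",
    "save_checkpoint",
    "load_checkpoint",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


_MAC_TALLY: list[int] | None = None


@contextlib.contextmanager
def tally_macs():
    """Context manager yielding a single-element list accumulating MACs."""
    global _MAC_TALLY
    prev = _MAC_TALLY
    _MAC_TALLY = [0]
    try:
        yield _MAC_TALLY
    finally:
        _MAC_TALLY = prev


def _add_macs(n: int):
    if _MAC_TALLY is not None:
        _MAC_TALLY[0] += int(n)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._parameters[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._parameters.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def get_submodule(self, path: str) -> "Module":
        mod = self
        for part in path.split("."):
            if part:
                mod = mod._modules[part]
        return mod

    def set_submodule(self, path: str, new: "Module"):
        parts = path.split(".")
        parent = self.get_submodule(".".join(parts[:-1]))
        parent._modules[parts[-1]] = new
        object.__setattr__(parent, parts[-1], new)

    # -- state ---------------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for prefix, mod in self.named_modules():
            for name, p in mod._parameters.items():
                out[f"{prefix}.{name}" if prefix else name] = p.data
            for name, b in mod._buffers.items():
                out[f"{prefix}.{name}" if prefix else name] = b
        return out

    def load_state_dict(self, state: dict):
        own = {}
        for prefix, mod in self.named_modules():
            for name, p in mod._parameters.items():
                own[f"{prefix}.{name}" if prefix else name] = ("p", mod, name, p)
            for name in mod._buffers:
                own[f"{prefix}.{name}" if prefix else name] = ("b", mod, name, None)
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(unexpected)}")
        for key, (kind, mod, name, p) in own.items():
            arr = np.asarray(state[key])
            if kind == "p":
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {arr.shape}")
                p.data = arr.astype(np.float32)
            else:
                mod._buffers[name][...] = arr

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._modules.values())

    def __getitem__(self, i):
        return list(self._modules.values())[i]

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        padding_mode: str = "zeros",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        self.padding_mode = padding_mode
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
            padding_mode=self.padding_mode,
        )
        _, _, Hout, Wout = y.shape
        _add_macs(
            (self.in_channels // self.groups)
            * self.kernel_size
            * self.kernel_size
            * self.out_channels
            * Hout
            * Wout
        )
        return y


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(
            x,
            self.weight,
            self.bias,
            self._buffers["running_mean"],
            self._buffers["running_var"],
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_fan_in_uniform(rng, (out_features, in_features), in_features))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        _add_macs(self.in_features * self.out_features)
        return T.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0, count_include_pad=False):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.count_include_pad = count_include_pad

    def forward(self, x):
        return T.avg_pool2d(x, self.kernel_size, self.stride, self.padding, self.count_include_pad)


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size):
        super().__init__()
        self.output_size = output_size

    def forward(self, x):
        return T.adaptive_avg_pool2d(x, self.output_size)


def save_checkpoint(model: Module, path: str):
    """Serialise all parameters and buffers to an ``.npz`` container."""
    np.savez(path, **{k: v for k, v in model.state_dict().items()})


def load_checkpoint(model: Module, path: str):
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
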