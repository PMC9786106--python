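"""Layer modules for the NumPy autodiff backend."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, ModuleList):
                yield from v

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_parameters(f"{full}.{i}.")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpointing -------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"{name}.running_mean"].astype(np.float32).copy()
                m.running_var = state[f"{name}.running_var"].astype(np.float32).copy()

    def _named_modules(self, prefix: str = "") -> Iterator[tuple]:
        yield prefix.rstrip("."), self
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m._named_modules(f"{prefix}{name}.{i}.")


class ModuleList(list):
    """A plain list whose Module elements are visible to parameter discovery."""


class Conv2d(Module):
    """Stride-1 convolution with He-initialised weights and `same`-style padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Kernel-2, stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_channels)
        self.weight = Parameter(rng.normal(0.0, scale, (in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class GroupNorm(Module):
    """Group normalisation: per-sample statistics over (C/g, H, W).

    Batch-size independent and identical in train and eval mode, which keeps
    a pipeline whose input distribution is deliberately bimodal (e.g. color
    complementation of half the batches) consistent between training and
    inference.  ``groups=1`` normalises over all channels jointly.
    """

    def __init__(self, channels: int, groups: int = 1, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.groups = groups
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - mu) * ((var + self.eps) ** -0.5)).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.maxpool2x2(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class ConvBNReLU(Module):
    """Conv -> normalisation -> ReLU, the standard unit inside encoder blocks.

    Normalisation is GroupNorm: deterministic at inference and batch-size
    independent, which the small-batch training schedules here require.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        pad = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(in_channels, out_channels, kernel_size,
                           padding=pad, dilation=dilation, bias=False, rng=rng)
        self.bn = GroupNorm(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
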