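"""Neural-network modules built on the autodiff tensor.

Layout convention is NCHW for feature maps and (batch, tokens, width) for
token sequences. Every module draws its initial weights from the
``numpy.random.Generator`` passed at construction, so a seeded generator
makes the whole model build deterministic.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, parameter census."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, buf in self.named_buffers():
            state[f"{name}__buffer"] = buf.copy()
        return state

    def named_buffers(self, prefix=""):
        for m_name, m in self._named_modules():
            for k in getattr(m, "_buffers", ()):
                yield f"{m_name}{k}", getattr(m, k)

    def _named_modules(self, prefix=""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64)
        for m_name, m in self._named_modules():
            for k in getattr(m, "_buffers", ()):
                key = f"{m_name}{k}__buffer"
                if key in state:
                    setattr(m, k, np.array(state[key], dtype=np.float64))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.padding = kernel_size // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape((1, c, 1, 1))
        b = self.beta.reshape((1, c, 1, 1))
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last axis (token width)."""

    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class ReLU(Module):
    """Stateless; exists as a module so block layer censuses are auditable."""

    def __call__(self, x: Tensor) -> Tensor:
        return T.relu(x)


def relu(x: Tensor) -> Tensor:
    return T.relu(x)
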