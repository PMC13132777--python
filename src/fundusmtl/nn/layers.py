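"""Module/parameter containers and the layers used by the networks."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "ConvTranspose2d", "Linear",
           "Sequential", "ReLU", "BatchNorm2d"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight layer container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    _buffer_names: tuple = ()

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield f"{prefix}{name}", self, name
        for key, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(f"{prefix}{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{key}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization --------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state[name] = getattr(owner, attr).copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        buffers = {name: (owner, attr)
                   for name, owner, attr in self.named_buffers()}
        expected = set(own) | set(buffers)
        missing = expected - set(state)
        extra = set(state) - expected
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, (owner, attr) in buffers.items():
            arr = np.asarray(state[name], dtype=np.float32)
            setattr(owner, attr, arr.copy())

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_fan_in(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_fan_in((out_ch, in_ch, k, k),
                                           in_ch * k * k, rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 2,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_he_fan_in((in_ch, out_ch, k, k),
                                           in_ch * k * k, rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_fan_in((in_dim, out_dim), in_dim, rng))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalization for NCHW tensors.

    Training mode normalizes by batch statistics and updates running
    estimates (exponential moving average, momentum 0.1); eval mode uses the
    running estimates.  Statistics are deterministic given the batch
    composition, which the training loop seeds.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        # running stats are buffers, not parameters; persisted separately
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        x_hat = (x - mean) / ((var + self.eps) ** 0.5)
        return x_hat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
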