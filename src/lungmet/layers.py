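"""Neural-network building blocks on top of the autodiff engine.

Provides a tiny ``Module`` hierarchy (parameter registration, train/eval
mode, state dicts) plus the concrete layers the segmentation network uses:
dense and depthwise-separable convolutions, batch norm, dropout and the
Adam optimizer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "SeparableConv2d",
    "BatchNorm2d",
    "Dropout",
    "Adam",
]


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield (f"{prefix}{k}", v)

    def _named_modules(self, prefix: str = ""):
        yield (prefix, self)
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

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
            p.grad = None

    # buffers (running stats) are Module attributes named in _buffer_names
    _buffer_names: tuple = ()

    def state_dict(self) -> dict:
        state = {}
        for prefix, mod in self._named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{prefix}{k}"] = v.data.copy()
            for k in mod._buffer_names:
                state[f"{prefix}{k}"] = getattr(mod, k).copy()
        return state

    def load_state_dict(self, state: dict):
        for prefix, mod in self._named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.array(state[f"{prefix}{k}"], dtype=v.data.dtype)
            for k in mod._buffer_names:
                buf = getattr(mod, k)
                buf[...] = state[f"{prefix}{k}"]


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    """Dense stride-1 convolution with zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.pad = pad
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                               in_ch * kernel * kernel)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
            if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, pad=self.pad)


class SeparableConv2d(Module):
    """Depthwise 3x3 followed by pointwise 1x1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.depthwise = _he_init(rng, (in_ch, 3, 3), 9)
        self.pointwise = Conv2d(in_ch, out_ch, kernel=1, pad=0, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pointwise(ad.depthwise_conv2d(x, self.depthwise, pad=1))


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Uses the rng passed at init."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Adam:
    """Adam with externally supplied per-step learning rate."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
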