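"""Layer and optimizer primitives built on :mod:`htem.autodiff`.

Weight initialization follows the package defaults: truncated normal
(sigma 0.02, clipped at two sigma) for dense/attention matrices, fan-out
scaled normal for convolution kernels, ones/zeros for normalization scale
and shift.  Every initializer takes an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A learnable tensor; float32 by default so checkpoints are 4 bytes/weight."""

    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) resampled until within two standard deviations."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


def fanout_normal(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape)


class Module:
    """Base class: parameter discovery, train/eval mode, name census."""

    def __init__(self):
        self._training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def train(self):
        for m in self._submodules():
            m._training = True
        self._training = True
        return self

    def eval(self):
        for m in self._submodules():
            m._training = False
        self._training = False
        return self

    def _submodules(self):
        def walk(v):
            if isinstance(v, Module):
                yield v
                yield from v._submodules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)

        for v in vars(self).values():
            yield from walk(v)

    def named_parameters(self, prefix: str = ""):
        """Yield (name, Parameter) pairs, depth first, deterministic order."""
        def walk(name, v):
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    yield from walk(f"{name}.{i}", item)

        for key, v in vars(self).items():
            yield from walk(f"{prefix}{key}", v)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) - set(state)
            extra = set(state) - set(own)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Conv2d(Module):
    """NHWC convolution with square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator):
        super().__init__()
        fan_out = kernel * kernel * out_channels
        self.weight = Parameter(
            fanout_normal(rng, (kernel, kernel, in_channels, out_channels), fan_out))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int, padding: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_out = kernel * kernel
        self.weight = Parameter(fanout_normal(rng, (kernel, kernel, channels), fan_out))
        self.bias = Parameter(np.zeros(channels))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv2d(x, self.weight, self.bias,
                                   self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm2d(x, self.gamma, self.beta,
                               self.running_mean, self.running_var,
                               training=self._training, momentum=self.momentum)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params, lr: float = 0.002, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain SGD with optional momentum."""

    def __init__(self, params, lr: float = 0.002, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data = p.data - self.lr * self.buf[i]
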