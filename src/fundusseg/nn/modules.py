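"""Layer modules and the Adam optimizer for the numpy conv-net engine."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor


class Module:
    """Base class: child modules and parameters are discovered by attribute scan."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for it in items:
                if isinstance(it, Tensor) and it.requires_grad and id(it) not in seen:
                    seen.add(id(it))
                    params.append(it)
                elif isinstance(it, Module):
                    for p in it.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for it in items:
                if isinstance(it, Module):
                    mods.extend(it.modules())
        return mods

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

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running-stat arrays, in a stable order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        live = self.state_arrays()
        if len(live) != len(state):
            raise ValueError("state layout mismatch")
        for dst, src in zip(live, state):
            dst[...] = src

    def __call__(self, x):
        return self.forward(x)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(_he_normal(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(_he_normal(rng, (cin, cout, k, k), cin * k * k // (stride * stride)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class AvgPool2d(Module):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        return F.avg_pool2d(x, self.k)


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        return F.max_pool2d(x, self.k, self.stride, self.pad)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the standard bias correction; ``decay`` is L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps, self.decay = lr, beta1, beta2, eps, decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.decay:
                g = g + self.decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
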