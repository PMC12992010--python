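"""Neural-network layers, parameter management and the Adam optimizer.

Layers compose the primitives of :mod:`mganet.autograd`.  The design
mirrors the familiar Module/Parameter pattern: ``parameters()`` walks
the attribute tree, ``state_dict()``/``load_state_dict()`` move weights
by hierarchical name, and ``train()``/``eval()`` toggle batch-norm
behaviour.  Weight initialisation is explicit — every layer draws from
the ``numpy.random.Generator`` handed to its constructor, so a model is
a pure function of its config and seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Identity",
    "MaxPool2d",
    "Adam",
]


class Module:
    """Base class: tracks sub-modules, parameters and buffers by attribute."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from value.named_modules(sub)

    def named_parameters(self):
        for mpath, mod in self.named_modules():
            for name, value in vars(mod).items():
                if isinstance(value, Tensor) and value.requires_grad:
                    yield (f"{mpath}.{name}" if mpath else name), value

    def named_buffers(self):
        for mpath, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                yield (f"{mpath}.{name}" if mpath else name), getattr(mod, name)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True):
        for _, mod in self.named_modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            p.data = np.array(state[name], dtype=np.float64)
        for name, _ in self.named_buffers():
            mod_path, _, attr = name.rpartition(".")
            mod = self._module_at(mod_path)
            setattr(mod, attr, np.array(state[name], dtype=np.float64))

    def _module_at(self, path: str) -> "Module":
        mod = self
        if path:
            for part in path.split("."):
                mod = getattr(mod, part)
        return mod

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
        self._n = len(tuple(modules))

    def __len__(self):
        return self._n

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, str(i))

    def append(self, module: Module):
        setattr(self, str(self._n), module)
        self._n += 1


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Conv2d(Module):
    """2-D convolution with Kaiming-normal weight init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, num_ch: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)
        self.running_mean = np.zeros(num_ch)
        self.running_var = np.ones(num_ch)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel, self.stride, self.padding)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
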