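"""Layer and optimizer primitives built on the autograd core.

Mirrors the familiar ``Module`` idiom: parameters and sub-modules are
registered on attribute assignment, ``state_dict`` flattens parameters and
batch-norm running statistics into a name → array mapping for
checkpointing.  Weight initialization is explicit: every module that owns
weights takes a ``numpy.random.Generator`` so model construction is fully
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    def parameters(self):
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_entries(self, prefix=""):
        """Yield (name, array, is_param) for parameters and buffers."""
        for k, p in self._params.items():
            yield prefix + k, p, True
        for k, b in self._buffers.items():
            yield prefix + k, b, False
        for k, m in self._modules.items():
            yield from m.named_entries(prefix + k + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            name: (entry.data if is_param else entry).copy()
            for name, entry, is_param in self.named_entries()
        }

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, entry, is_param in self.named_entries():
            arr = state[name]
            if is_param:
                if entry.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                entry.data = arr.astype(entry.data.dtype, copy=True)
            else:
                entry[...] = arr

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    """Plain convolution (no norm/activation); Kaiming-normal init."""

    def __init__(self, c_in, c_out, kernel, rng: np.random.Generator,
                 stride=1, padding=None, dilation=1, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if padding is None:
            # "same" padding for stride 1 with odd kernels
            dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
            padding = (dh * (kh - 1) // 2, dw * (kw - 1) // 2)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = c_in * kh * kw
        w = rng.standard_normal((c_out, c_in, kh, kw)) * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training,
                               momentum=self.momentum, eps=self.eps)


class ConvBNSiLU(Module):
    """conv + batch norm + SiLU, the convolution block used throughout."""

    def __init__(self, c_in, c_out, kernel, rng, stride=1, padding=None,
                 dilation=1, act=True):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, rng, stride=stride,
                           padding=padding, dilation=dilation, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return ag.silu(x) if self.act else x


class AdamW:
    """Decoupled-weight-decay Adam."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD:
    """Plain gradient descent (used for small regression demonstrations)."""

    def __init__(self, params, lr=0.01):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
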