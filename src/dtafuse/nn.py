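"""Neural-network building blocks used by the affinity model.

Layers follow the usual conventions: sequences are laid out as
``(batch, length, channels)``; graphs as stacked node matrices
``(total_nodes, channels)`` with integer segment ids mapping nodes to
graphs.  Initialisation mirrors the fan-in uniform scheme common for
dense and convolutional layers.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with parameter traversal, train/eval mode and state dicts."""

    _buffer_names: tuple = ()

    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    # -- modes ----------------------------------------------------------------

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- checkpointing --------------------------------------------------------

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: np.array(buf, copy=True) for name, buf in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for name, _ in self.named_buffers():
            obj, attr = self._resolve_buffer(name)
            setattr(obj, attr, np.asarray(state[name], dtype=np.float64).copy())

    def _resolve_buffer(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)]  # pragma: no cover - lists resolved below
            else:
                value = getattr(obj, part, None)
                if value is None:
                    raise KeyError(dotted)
                obj = value
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_features),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    """Integer-code lookup table; code 0 is the padding row, frozen at zero."""

    def __init__(self, num_codes: int, dim: int, rng: np.random.Generator):
        super().__init__()
        table = rng.normal(0.0, 1.0 / np.sqrt(dim), (num_codes, dim))
        self.table = Tensor(table, requires_grad=True)
        mask = np.ones((num_codes, 1))
        mask[0] = 0.0
        self._pad_mask = Tensor(mask)

    def forward(self, codes: np.ndarray) -> Tensor:
        codes = np.asarray(codes)
        if codes.size and codes.max() >= self.table.data.shape[0]:
            pos = int(np.argmax(codes.reshape(-1) >= self.table.data.shape[0]))
            raise ValueError(f"code out of range at flat position {pos}")
        return ag.take(self.table * self._pad_mask, codes)


class Conv1d(Module):
    """Same-padded 1-D convolution over (batch, length, channels) input."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (kernel_size, in_channels, out_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        length = x.shape[1]
        xp = ag.pad_axis(x, axis=1, before=(k - 1) // 2, after=k // 2)
        y = None
        for j in range(k):
            term = ag.matmul(xp[:, j:j + length, :], self.weight[j])
            y = term if y is None else y + term
        return y + self.bias


class BatchNorm1d(Module):
    """Batch normalisation over axis 0 (rows = nodes or samples)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean)
            std = Tensor(np.sqrt(self.running_var + self.eps))
            xhat = (x - mu) / std
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Adam:
    """Adaptive-moments optimiser (bias-corrected first/second moments)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
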