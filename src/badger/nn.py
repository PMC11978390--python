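"""Neural-network building blocks (linear/MLP, multi-head attention, Adam).

Built on :mod:`badger._autodiff`.  Layers hold their parameters as
:class:`~badger._autodiff.Tensor` leaves with ``requires_grad=True``; a
module tree exposes them through :meth:`Module.parameters`.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

from ._autodiff import Tensor

__all__ = ["Module", "Linear", "MLP", "Dropout", "MultiheadAttention", "Adam"]


class Module:
    """Base class: tracks sub-modules and parameters, holds a train flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        self._params[name] = tensor
        object.__setattr__(self, name, tensor)
        return tensor

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield prefix + k, v
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0,1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MLP(Module):
    """Two-layer perceptron with GELU and dropout, the model's default fuser."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).gelu()))


class MultiheadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads over 2-D inputs.

    Queries are ``(n_q, d)``, keys/values ``(n_k, d)``.  Returns the attended
    values ``(n_q, d)`` and the head-averaged attention matrix ``(n_q, n_k)``.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads:
            raise ValueError("embedding dim must be divisible by number of heads")
        self.d, self.n_heads, self.d_head = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def _split(self, x: Tensor, n: int) -> Tensor:
        # (n, d) -> (heads, n, d_head)
        return x.reshape(n, self.n_heads, self.d_head).transpose(1, 0, 2)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor
                 ) -> tuple[Tensor, Tensor]:
        n_q, n_k = query.shape[0], key.shape[0]
        q = self._split(self.wq(query), n_q)
        k = self._split(self.wk(key), n_k)
        v = self._split(self.wv(value), n_k)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)              # (heads, n_q, n_k)
        ctx = attn @ v                              # (heads, n_q, d_head)
        ctx = ctx.transpose(1, 0, 2).reshape(n_q, self.d)
        return self.wo(ctx), attn.mean(axis=0)


class Adam:
    """Standard Adam optimizer (bias-corrected moments)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: Optional[float] = 5.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
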