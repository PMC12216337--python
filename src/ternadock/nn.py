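"""Small neural-network building blocks on top of :mod:`ternadock.autodiff`.

Provides parameterised layers (Linear, MLP, Embedding), a parameter
registry, and an Adam optimizer with gradient-norm clipping.  Weight
initialisation is Glorot-uniform driven by an explicit
``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, relu


class Module:
    """Base class: collects ``Tensor`` parameters from attributes, recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def zero_all(self) -> None:
        """Zero every parameter in place (used by identity-contract tests)."""
        for p in self.parameters():
            p.data[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data[...] = a


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, zero_init: bool = False):
        w = np.zeros((n_in, n_out)) if zero_init else glorot(rng, n_in, n_out)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Two-hidden-layer perceptron with ReLU; optional zero-initialised output."""

    def __init__(self, rng, n_in: int, n_hidden: int, n_out: int, zero_out: bool = False):
        self.fc1 = Linear(rng, n_in, n_hidden)
        self.fc2 = Linear(rng, n_hidden, n_out, zero_init=zero_out)

    def __call__(self, *inputs: Tensor) -> Tensor:
        x = inputs[0] if len(inputs) == 1 else concatenate(inputs, axis=-1)
        return self.fc2(relu(self.fc1(x)))


class Embedding(Module):
    def __init__(self, rng, n_items: int, dim: int, scale: float = 0.1):
        self.table = Tensor(rng.normal(0.0, scale, size=(n_items, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx, dtype=int)]


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
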