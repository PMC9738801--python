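"""Small neural-network building blocks on the autodiff core.

Layers hold float64 parameters; initialization is driven by an explicit
``numpy.random.Generator`` so every model in the package is reproducible
from a seed. Checkpoints are plain dicts of arrays (``state_dict``) that
can be written with :func:`numpy.savez`.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from ._autodiff import Tensor, logsumexp

__all__ = [
    "Module", "Linear", "MLP", "Adam",
    "cross_entropy", "mse_loss",
]


class Module:
    """Base class: parameter registry plus state-dict (de)serialization."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    params[f"{name}.{sub}"] = p
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    """Affine map ``x @ W.T + b`` with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.W = Tensor(_glorot(rng, in_dim, out_dim, (out_dim, in_dim)), requires_grad=True)
        if bias:
            # nonzero bias init keeps ReLU stacks from emitting exactly-zero
            # rows at initialization (which cosine similarity cannot handle)
            bound = 1.0 / np.sqrt(in_dim)
            self.b = Tensor(rng.uniform(-bound, bound, size=out_dim),
                            requires_grad=True)
        else:
            self.b = None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W.T
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Fully connected stack with ReLU between layers (none after the last)."""

    def __init__(self, dims: Iterable[int], rng: np.random.Generator, bias: bool = True):
        dims = list(dims)
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.n_layers = len(dims) - 1
        for i in range(self.n_layers):
            setattr(self, f"layer{i}", Linear(dims[i], dims[i + 1], rng, bias=bias))

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = getattr(self, f"layer{i}")(x)
            if i < self.n_layers - 1:
                x = x.relu()
        return x


class Adam:
    """Adam with optional L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids."""
    labels = np.asarray(labels, dtype=int)
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    lse = logsumexp(logits, axis=1)
    picked = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return (diff * diff).mean()
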