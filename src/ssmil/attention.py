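"""Gated attention-based MIL pooling.

A bag is one slide's set of instance embeddings h_k. The gated attention
mechanism scores each instance with

    a_k = softmax_k( w^T ( tanh(V h_k) * sigm(U h_k) ) )

(elementwise product between the tanh and sigmoid branches) and pools the
bag into a single slide-level vector

    z = sum_k a_k h_k .

Both a functional NumPy surface (:func:`attention_weights`, :func:`pool`)
and a trainable module (:class:`GatedAttentionPooling`) share this math;
the module additionally supports batched pooling of equally sized bags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, softmax
from .nn import Module, _glorot

__all__ = [
    "Bag", "GatedAttentionParams", "BagEncoding",
    "attention_weights", "pool", "GatedAttentionPooling",
]


@dataclass
class Bag:
    """One slide's instances: a (K, embedding_dim) matrix plus optional label.

    ``instance_clusters`` (optional) records, per instance, the latent
    cluster it was generated from — synthetic data only, used to interrogate
    what attention learns.
    """

    slide_id: str
    instances: np.ndarray
    label: float | int | None = None
    instance_clusters: np.ndarray | None = None

    def __post_init__(self):
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2:
            raise ValueError("a bag needs a (K, D) instance matrix")

    @property
    def size(self) -> int:
        return self.instances.shape[0]

    @property
    def dim(self) -> int:
        return self.instances.shape[1]


@dataclass
class GatedAttentionParams:
    """Parameters (V, U, w) of the gated attention scorer."""

    V: np.ndarray
    U: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.V.shape != self.U.shape:
            raise ValueError("V and U must share shape (attention_dim, embedding_dim)")
        if self.w.shape != (self.V.shape[0],):
            raise ValueError("w length must equal attention_dim")

    @property
    def attention_dim(self) -> int:
        return self.V.shape[0]

    @classmethod
    def random(cls, embedding_dim: int, attention_dim: int,
               rng: np.random.Generator) -> "GatedAttentionParams":
        return cls(
            V=_glorot(rng, embedding_dim, attention_dim, (attention_dim, embedding_dim)),
            U=_glorot(rng, embedding_dim, attention_dim, (attention_dim, embedding_dim)),
            w=_glorot(rng, attention_dim, 1, (attention_dim,)),
        )


@dataclass
class BagEncoding:
    """Pooled slide-level vector z plus the attention weights that formed it."""

    z: np.ndarray
    attention: np.ndarray = field(repr=False)


def _logits(H: np.ndarray, params: GatedAttentionParams) -> np.ndarray:
    gate = np.tanh(H @ params.V.T) * (1.0 / (1.0 + np.exp(-(H @ params.U.T))))
    return gate @ params.w


def attention_weights(bag: Bag | np.ndarray, params: GatedAttentionParams) -> np.ndarray:
    """Softmax-normalized attention weights a_k of a bag (sum to 1)."""
    H = bag.instances if isinstance(bag, Bag) else np.asarray(bag, dtype=np.float64)
    if H.shape[0] < 1:
        raise ValueError("cannot score an empty bag")
    if H.shape[1] != params.V.shape[1]:
        raise ValueError(
            f"embedding dim {H.shape[1]} does not match parameters ({params.V.shape[1]})")
    logits = _logits(H, params)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def pool(bag: Bag | np.ndarray, params: GatedAttentionParams) -> BagEncoding:
    """Attention-weighted pooling of a bag into one slide-level vector."""
    H = bag.instances if isinstance(bag, Bag) else np.asarray(bag, dtype=np.float64)
    if H.shape[0] < 1:
        raise ValueError("cannot pool an empty bag")
    a = attention_weights(H, params)
    return BagEncoding(z=a @ H, attention=a)


class GatedAttentionPooling(Module):
    """Trainable gated attention pooling (no bias terms by default)."""

    def __init__(self, embedding_dim: int, attention_dim: int,
                 rng: np.random.Generator, bias: bool = False):
        self.embedding_dim = embedding_dim
        self.attention_dim = attention_dim
        self.V = Tensor(_glorot(rng, embedding_dim, attention_dim,
                                (attention_dim, embedding_dim)), requires_grad=True)
        self.U = Tensor(_glorot(rng, embedding_dim, attention_dim,
                                (attention_dim, embedding_dim)), requires_grad=True)
        self.w = Tensor(_glorot(rng, attention_dim, 1, (attention_dim, 1)), requires_grad=True)
        self.bV = Tensor(np.zeros(attention_dim), requires_grad=True) if bias else None
        self.bU = Tensor(np.zeros(attention_dim), requires_grad=True) if bias else None

    def _gate(self, H2: Tensor) -> Tensor:
        pre_v = H2 @ self.V.T
        pre_u = H2 @ self.U.T
        if self.bV is not None:
            pre_v = pre_v + self.bV
            pre_u = pre_u + self.bU
        return pre_v.tanh() * pre_u.sigmoid()

    def forward(self, H: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """Pool one bag (K, D) -> (z (D,), attention (K,))."""
        Ht = H if isinstance(H, Tensor) else Tensor(H)
        logits = (self._gate(Ht) @ self.w).reshape(1, Ht.shape[0])
        a = softmax(logits, axis=1)  # (1, K)
        z = (a @ Ht).reshape(Ht.shape[1])
        return z, a.reshape(Ht.shape[0])

    def forward_batch(self, H3: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """Pool B equally sized bags (B, K, D) -> (z (B, D), attention (B, K))."""
        Ht = H3 if isinstance(H3, Tensor) else Tensor(H3)
        b, k, d = Ht.shape
        logits = (self._gate(Ht.reshape(b * k, d)) @ self.w).reshape(b, k)
        a = softmax(logits, axis=1)  # (B, K)
        z = (a.reshape(b, k, 1) * Ht).sum(axis=1)
        return z, a

    def to_params(self) -> GatedAttentionParams:
        return GatedAttentionParams(V=self.V.data.copy(), U=self.U.data.copy(),
                                    w=self.w.data.reshape(-1).copy())
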