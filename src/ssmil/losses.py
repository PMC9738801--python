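"""NT-Xent: normalized temperature-scaled cross-entropy contrastive loss.

The same loss drives both stages of the pipeline — tile-level contrastive
pretraining (temperature 0.5 by default) and slide-level contrastive MIL
(temperature 1.0). For each anchor i with positive partner p(i),

    loss_i = -log  exp(cos(z_i, z_p(i)) / tau)
                  ---------------------------------
                  sum_{k != i} exp(cos(z_i, z_k) / tau)

and the batch loss is the mean over all 2N anchors. Every non-positive
item in the batch acts as a negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, l2_normalize, logsumexp

__all__ = ["ContrastiveBatch", "nt_xent", "nt_xent_from_tensor", "pair_index_for_stacked_views"]

_NEG_INF = -1e9


@dataclass
class ContrastiveBatch:
    """2N projection vectors plus the involution pairing positives.

    ``pair_index[i] = j`` means (i, j) is a positive pair; the mapping must
    be an involution without fixed points covering all 2N items.
    """

    projections: np.ndarray
    pair_index: np.ndarray
    temperature: float = 1.0

    def __post_init__(self):
        self.projections = np.asarray(self.projections, dtype=np.float64)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        n = self.projections.shape[0]
        if self.pair_index.shape != (n,):
            raise ValueError("pair_index must have one entry per projection")
        idx = np.arange(n)
        if np.any(self.pair_index == idx):
            raise ValueError("pair_index must have no fixed points")
        if not np.array_equal(self.pair_index[self.pair_index], idx):
            raise ValueError("pair_index must be an involution")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def pair_index_for_stacked_views(n_pairs: int) -> np.ndarray:
    """Pairing for the layout [view1 of all N items; view2 of all N items]."""
    return np.concatenate([np.arange(n_pairs) + n_pairs, np.arange(n_pairs)])


def nt_xent_from_tensor(z: Tensor, pair_index: np.ndarray, temperature: float) -> Tensor:
    """Differentiable NT-Xent on a (2N, P) tensor of projections."""
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least one positive pair (2 items)")
    zn = l2_normalize(z, axis=1)
    sim = (zn @ zn.T) * (1.0 / temperature)
    mask = np.zeros((n, n))
    np.fill_diagonal(mask, _NEG_INF)  # an item is never its own negative
    denom = logsumexp(sim + Tensor(mask), axis=1)
    pos_onehot = np.zeros((n, n))
    pos_onehot[np.arange(n), pair_index] = 1.0
    pos = (sim * Tensor(pos_onehot)).sum(axis=1)
    return (denom - pos).mean()


def nt_xent(batch: ContrastiveBatch) -> float:
    """NT-Xent loss of a batch of paired projections (scalar)."""
    return nt_xent_from_tensor(
        Tensor(batch.projections), batch.pair_index, batch.temperature
    ).item()
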