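"""Contrastive MIL: slide-level representation learning without labels.

Each slide's bag of tile embeddings is independently subsampled (with
replacement, one quarter of the instances by default) into two *views*.
A view acts as a "transformation" of the slide, the way a crop or color
jitter transforms an image. Both views are pooled by gated attention,
projected, and trained with NT-Xent (temperature 1.0) so views of the same
slide attract and views of different slides repel. The learned slide
representation is the attention-pooled encoding z of the *full* bag, with
the projection head discarded.

Training follows Adam with learning rate 2e-4, weight decay 1e-5 and
batches of up to 70 slides (140 views); the checkpoint with the lowest
validation loss is kept, with validation views fixed by seed so selection
is reproducible.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from .attention import Bag, GatedAttentionPooling
from .losses import nt_xent_from_tensor, pair_index_for_stacked_views
from .nn import MLP, Adam, Module

__all__ = ["BagView", "SSMILModel", "SSMILSchedule", "subsample_bag",
           "make_view_pairs", "forward_view", "train_ssmil",
           "slide_representation", "represent_bags",
           "save_model", "load_model"]

DEFAULT_FRACTION = 0.25


@dataclass
class BagView:
    """A seeded, with-replacement subsample of a bag — one slide 'view'."""

    slide_id: str
    instance_indices: np.ndarray = field(repr=False)
    view_seed: int = 0

    def __post_init__(self):
        self.instance_indices = np.asarray(self.instance_indices, dtype=int)
        if self.instance_indices.ndim != 1 or self.instance_indices.size < 1:
            raise ValueError("a view needs at least one instance index")


def view_size(bag_size: int, fraction: float = DEFAULT_FRACTION) -> int:
    """Number of instances in a view: max(1, round(fraction * K))."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, int(round(fraction * bag_size)))


def subsample_bag(bag: Bag, fraction: float = DEFAULT_FRACTION,
                  seed: int = 0) -> BagView:
    """One with-replacement subsample of a bag (a slide 'transformation')."""
    if bag.size < 1:
        raise ValueError("cannot subsample an empty bag")
    m = view_size(bag.size, fraction)
    rng = np.random.default_rng(seed)
    return BagView(slide_id=bag.slide_id,
                   instance_indices=rng.integers(0, bag.size, size=m),
                   view_seed=seed)


def _slide_tag(slide_id: str) -> int:
    return zlib.crc32(slide_id.encode())


def make_view_pairs(bags: Sequence[Bag], fraction: float = DEFAULT_FRACTION,
                    epoch_seed: int = 0) -> list[tuple[BagView, BagView]]:
    """Two independently seeded views per slide; seeds derive from
    (epoch_seed, slide_id, view index) so pairs differ across epochs."""
    if len(bags) < 2:
        raise ValueError("need at least 2 slides so negatives exist")
    pairs = []
    for bag in bags:
        seeds = [int(np.random.SeedSequence(
            [epoch_seed, _slide_tag(bag.slide_id), v]).generate_state(1)[0] % (2 ** 31))
            for v in (0, 1)]
        pairs.append((subsample_bag(bag, fraction, seeds[0]),
                      subsample_bag(bag, fraction, seeds[1])))
    return pairs


class SSMILModel(Module):
    """Gated attention pooling + projection head, trained contrastively."""

    def __init__(self, embedding_dim: int, attention_dim: int = 128,
                 mil_projection_dim: int = 128, temperature: float = 1.0,
                 rng: np.random.Generator | None = None,
                 use_projection_as_representation: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embedding_dim = embedding_dim
        self.temperature = temperature
        self.use_projection_as_representation = use_projection_as_representation
        self.attention = GatedAttentionPooling(embedding_dim, attention_dim, rng)
        self.projection = MLP([embedding_dim, embedding_dim, mil_projection_dim], rng)

    def forward_views_batch(self, stacked: np.ndarray) -> Tensor:
        """(B, m, D) gathered view instances -> (B, projection_dim)."""
        z, _ = self.attention.forward_batch(stacked)
        return self.projection(z)

    def config(self) -> dict:
        return {
            "embedding_dim": self.embedding_dim,
            "attention_dim": self.attention.attention_dim,
            "mil_projection_dim": self.projection.layer1.out_dim,
            "temperature": self.temperature,
            "use_projection_as_representation": self.use_projection_as_representation,
        }


def forward_view(model: SSMILModel, bag: Bag, view: BagView) -> np.ndarray:
    """Project one view: gather (duplicates repeated), pool, project."""
    idx = view.instance_indices
    if idx.min() < 0 or idx.max() >= bag.size:
        raise IndexError("view indices out of range for bag")
    z, _ = model.attention.forward(bag.instances[idx])
    return model.projection(z.reshape(1, -1)).data[0]


def slide_representation(model: SSMILModel, bag: Bag) -> np.ndarray:
    """Slide-level feature vector: pool the FULL bag with trained attention.

    The pre-projection pooled encoding z is returned (SimCLR convention of
    discarding the projection head), unless the model was configured to
    use the projection output instead.
    """
    if bag.size < 1:
        raise ValueError("cannot represent an empty bag")
    z, _ = model.attention.forward(bag.instances)
    if model.use_projection_as_representation:
        return model.projection(z.reshape(1, -1)).data[0]
    return z.data.copy()


def represent_bags(model: SSMILModel, bags: Sequence[Bag]) -> np.ndarray:
    return np.stack([slide_representation(model, b) for b in bags])


@dataclass
class SSMILSchedule:
    """Contrastive MIL training schedule."""

    epochs: int = 1000
    lr: float = 2e-4
    weight_decay: float = 1e-5
    batch_size: int = 70          # slides per batch (2 views each)
    fraction: float = DEFAULT_FRACTION
    temperature: float = 1.0
    seed: int = 0
    val_seed: int = 202            # fixes validation views across epochs
    eval_every: int = 1


def _views_loss(model: SSMILModel, bags: Sequence[Bag],
                pairs: list[tuple[BagView, BagView]], temperature: float) -> Tensor:
    sizes = {v.instance_indices.size for pair in pairs for v in pair}
    if len(sizes) == 1:
        stacked = np.stack(
            [bags[i].instances[pairs[i][0].instance_indices] for i in range(len(bags))]
            + [bags[i].instances[pairs[i][1].instance_indices] for i in range(len(bags))])
        z = model.forward_views_batch(stacked)
    else:  # unequal bag sizes: pool views one by one
        zs = []
        for v_idx in (0, 1):
            for i, bag in enumerate(bags):
                zv, _ = model.attention.forward(
                    bag.instances[pairs[i][v_idx].instance_indices])
                zs.append(model.projection(zv.reshape(1, -1)))
        z = _stack_rows(zs)
    return nt_xent_from_tensor(z, pair_index_for_stacked_views(len(bags)), temperature)


def _stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack (1, P) tensors into (n, P) keeping gradients flowing."""
    n = len(rows)
    p = rows[0].shape[1]
    padded = []
    for i, r in enumerate(rows):
        onehot = np.zeros((n, 1))
        onehot[i, 0] = 1.0
        padded.append(Tensor(onehot) @ r)
    out = padded[0]
    for r in padded[1:]:
        out = out + r
    return out


def train_ssmil(train_bags: Sequence[Bag], val_bags: Sequence[Bag] | None = None,
                model: SSMILModel | None = None,
                schedule: SSMILSchedule | None = None) -> tuple[SSMILModel, dict]:
    """Train contrastive MIL; keep the lowest-validation-loss checkpoint.

    ``train_bags`` and ``val_bags`` must be disjoint by slide id. When no
    validation set is given, checkpoint selection falls back to training
    loss.
    """
    schedule = schedule or SSMILSchedule()
    if len(train_bags) < 2:
        raise ValueError("need at least 2 training slides")
    if val_bags:
        overlap = {b.slide_id for b in train_bags} & {b.slide_id for b in val_bags}
        if overlap:
            raise ValueError(f"train/validation slides overlap: {sorted(overlap)[:3]}")
    root = np.random.SeedSequence(schedule.seed)
    init_seed, shuffle_entropy = (int(s) for s in root.generate_state(2) % (2 ** 31))
    if model is None:
        model = SSMILModel(embedding_dim=train_bags[0].dim,
                           temperature=schedule.temperature,
                           rng=np.random.default_rng(init_seed))
    log: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    if schedule.epochs == 0:
        return model, log

    optimizer = Adam(model.parameters(), lr=schedule.lr,
                     weight_decay=schedule.weight_decay)
    best_val, best_state = np.inf, None
    val_pairs = (make_view_pairs(val_bags, schedule.fraction, schedule.val_seed)
                 if val_bags else None)

    for epoch in range(schedule.epochs):
        erng = np.random.default_rng((shuffle_entropy + epoch) % (2 ** 31))
        order = erng.permutation(len(train_bags))
        epoch_pairs_seed = int(erng.integers(0, 2 ** 30))
        losses = []
        for start in range(0, len(order), schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            if len(idx) < 2:
                continue  # negatives must span at least one other slide
            batch = [train_bags[i] for i in idx]
            pairs = make_view_pairs(batch, schedule.fraction,
                                    epoch_seed=epoch_pairs_seed + epoch)
            loss = _views_loss(model, batch, pairs, schedule.temperature)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        train_loss = float(np.mean(losses)) if losses else np.nan
        log["train_loss"].append(train_loss)
        if val_pairs is not None and epoch % schedule.eval_every == 0:
            val_loss = _views_loss(model, val_bags, val_pairs,
                                   schedule.temperature).item()
        else:
            val_loss = train_loss
        log["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            log["best_epoch"] = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    # soft diagnostic: contrastive MIL self-regularizes — unlike supervised
    # training, its loss converges well above zero
    n_batch = min(schedule.batch_size, len(train_bags))
    log["final_train_loss"] = log["train_loss"][-1]
    log["loss_floor_reference"] = 0.1 * float(np.log(2 * n_batch - 1))
    return model, log


# ----------------------------------------------------------------- storage

def save_model(path: str | Path, model: SSMILModel) -> None:
    import json

    state = {k: v.tolist() for k, v in model.state_dict().items()}
    payload = {"config": model.config(), "state": state}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SSMILModel:
    import json

    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    model = SSMILModel(embedding_dim=cfg["embedding_dim"],
                       attention_dim=cfg["attention_dim"],
                       mil_projection_dim=cfg["mil_projection_dim"],
                       temperature=cfg["temperature"],
                       use_projection_as_representation=cfg[
                           "use_projection_as_representation"])
    model.load_state_dict({k: np.asarray(v) for k, v in payload["state"].items()})
    return model
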