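"""Contrastive pretraining of the tile encoder (SSL / SSLn).

Two augmented views of a tile form a positive pair; all other views in the
batch are negatives (SimCLR-style, NT-Xent with tile-level temperature 0.5).
The transformation family reflects the invariances of histopathology:
rotation, rescaling, color/contrast jitter, and — in SSLn mode — *adjacency*:
one view is drawn from a randomly chosen grid neighbor of the anchor tile,
because neighboring tissue is very likely the same microanatomy.

The embedding used downstream is the encoder output h; the projection head
exists only to shape the contrastive loss and is discarded after
pretraining (SimCLR convention).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from ._autodiff import Tensor
from .attention import Bag
from .losses import nt_xent_from_tensor, pair_index_for_stacked_views
from .nn import MLP, Adam, Module
from .tiling import TileGrid, TileRecord, extract_tile, neighbors, sample_tiles

__all__ = [
    "AugmentationPolicy", "EncoderSpec", "TileEncoder", "SSLSchedule",
    "augment", "make_positive_pair", "PositivePair",
    "train_tile_encoder", "embed_slide",
]


@dataclass
class AugmentationPolicy:
    """Family of tile transformations sampled independently per view."""

    rotations: tuple[int, ...] = (0, 90, 180, 270)
    scale_jitter: tuple[float, float] | None = (0.75, 1.25)
    brightness: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    contrast: float = 0.2
    use_neighbor: bool = False
    # three-view SSLn: contrast anchor-vs-anchor AND anchor-vs-neighbor
    # (losses averaged) instead of the two-view neighbor-only form
    three_view: bool = False

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(rotations=(0,), scale_jitter=None, brightness=0.0,
                   saturation=0.0, hue=0.0, contrast=0.0, use_neighbor=False)

    @property
    def is_identity(self) -> bool:
        return (tuple(self.rotations) in ((), (0,))
                and (self.scale_jitter is None or self.scale_jitter == (1.0, 1.0))
                and self.brightness == self.saturation == self.hue == self.contrast == 0.0)


def _resize_keep_shape(tile: np.ndarray, factor: float) -> np.ndarray:
    """Rescale by ``factor`` then center-crop / reflect-pad back to shape."""
    from skimage.transform import rescale

    h, w = tile.shape[:2]
    out = rescale(tile, factor, channel_axis=2, anti_aliasing=factor < 1)
    oh, ow = out.shape[:2]
    if oh >= h:
        r0, c0 = (oh - h) // 2, (ow - w) // 2
        return out[r0:r0 + h, c0:c0 + w]
    pr, pc = h - oh, w - ow
    return np.pad(out, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2), (0, 0)),
                  mode="reflect")


def augment(tile: np.ndarray, policy: AugmentationPolicy, seed: int) -> np.ndarray:
    """Seeded composition of independently sampled transforms from ``policy``."""
    tile = np.asarray(tile, dtype=np.float64)
    if policy.is_identity:
        return tile.copy()
    rng = np.random.default_rng(seed)
    out = tile
    if policy.rotations and tuple(policy.rotations) != (0,):
        deg = int(rng.choice(policy.rotations))
        if deg % 90 != 0:
            raise ValueError("rotations must be multiples of 90 degrees")
        if deg % 360:
            out = np.rot90(out, k=(deg // 90) % 4)
    if policy.scale_jitter is not None and policy.scale_jitter != (1.0, 1.0):
        out = _resize_keep_shape(out, rng.uniform(*policy.scale_jitter))
    if policy.brightness > 0:
        out = out * (1.0 + rng.uniform(-policy.brightness, policy.brightness))
    if policy.contrast > 0:
        m = out.mean()
        out = (out - m) * (1.0 + rng.uniform(-policy.contrast, policy.contrast)) + m
    if policy.saturation > 0 or policy.hue > 0:
        from skimage.color import hsv2rgb, rgb2hsv

        hsv = rgb2hsv(np.clip(out, 0, 1))
        if policy.hue > 0:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue, policy.hue)) % 1.0
        if policy.saturation > 0:
            hsv[..., 1] = np.clip(
                hsv[..., 1] * (1.0 + rng.uniform(-policy.saturation, policy.saturation)),
                0, 1)
        out = hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0)


class PositivePair(NamedTuple):
    view1: np.ndarray
    view2: np.ndarray
    source1: TileRecord
    source2: TileRecord


def make_positive_pair(record: TileRecord, grid: TileGrid, policy: AugmentationPolicy,
                       raster: np.ndarray, seed: int) -> PositivePair:
    """Two views of an anchor tile.

    SSL: both views are augmentations of the anchor. SSLn: the second view
    is an augmentation of a uniformly chosen retained neighbor (Chebyshev
    distance 1), falling back to the anchor when none is retained.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2 ** 31, size=3)
    anchor = extract_tile(raster, record)
    source2 = record
    if policy.use_neighbor:
        nbrs = neighbors(grid, record)
        if nbrs:
            source2 = nbrs[rng.integers(0, len(nbrs))]
    pixels2 = anchor if source2 is record else extract_tile(raster, source2)
    return PositivePair(view1=augment(anchor, policy, int(s1)),
                        view2=augment(pixels2, policy, int(s2)),
                        source1=record, source2=source2)


# ----------------------------------------------------------------- encoders

@dataclass
class EncoderSpec:
    """Backbone + head dimensions of the tile encoder.

    The registered desk-scale backbone, ``pooled-mlp``, block-averages the
    tile to a coarse pixel grid and embeds it with a small MLP — enough to
    separate procedural textures in seconds on one CPU. Backbone choice is
    a config switch; unknown identifiers raise.
    """

    backbone: str = "pooled-mlp"
    embedding_dim: int = 32
    projection_dim: int = 128
    projection_depth: int = 2
    hidden_dim: int = 128
    pool_grid: int = 8

    def build(self, rng: np.random.Generator) -> "TileEncoder":
        if self.backbone != "pooled-mlp":
            raise NotImplementedError(
                f"backbone {self.backbone!r} is not registered; available: 'pooled-mlp'")
        return TileEncoder(self, rng)


class TileEncoder(Module):
    """Encoder f (features -> h) plus projection head g (h -> z)."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        in_dim = spec.pool_grid * spec.pool_grid * 3
        self.encoder = MLP([in_dim, spec.hidden_dim, spec.embedding_dim], rng)
        proj_dims = [spec.embedding_dim] * spec.projection_depth + [spec.projection_dim]
        self.projection = MLP(proj_dims, rng)

    # -- preprocessing ------------------------------------------------------
    def preprocess(self, tiles: np.ndarray) -> np.ndarray:
        """Block-average (B, T, T, 3) tiles to flat (B, g*g*3) features."""
        tiles = np.asarray(tiles, dtype=np.float64)
        if tiles.ndim == 3:
            tiles = tiles[None]
        b, h, w, _ = tiles.shape
        g = self.spec.pool_grid
        if h % g == 0 and w % g == 0:
            pooled = tiles.reshape(b, g, h // g, g, w // g, 3).mean(axis=(2, 4))
        else:
            from skimage.transform import resize

            pooled = np.stack([resize(t, (g, g, 3), anti_aliasing=True) for t in tiles])
        return pooled.reshape(b, -1)

    # -- graph-building forward passes -------------------------------------
    def embed(self, features: Tensor) -> Tensor:
        return self.encoder(features)

    def project(self, h: Tensor) -> Tensor:
        return self.projection(h)

    # -- inference ----------------------------------------------------------
    def embed_tiles(self, tiles: np.ndarray) -> np.ndarray:
        """Deterministic h embeddings of raw tiles (inference mode)."""
        return self.embed(Tensor(self.preprocess(tiles))).data


@dataclass
class SSLSchedule:
    """Training schedule for tile-level contrastive pretraining."""

    epochs: int = 20
    patience: int = 5
    lr: float = 0.001
    batch_size: int = 256
    temperature: float = 0.5
    tiles_per_slide: int = 1000
    val_fraction: float = 0.2
    seed: int = 0


def train_tile_encoder(slides: Sequence[tuple[TileGrid, np.ndarray]],
                       policy: AugmentationPolicy,
                       spec: EncoderSpec,
                       schedule: SSLSchedule,
                       encoder: TileEncoder | None = None,
                       ) -> tuple[TileEncoder, dict]:
    """Contrastively pretrain the tile encoder on sampled tiles.

    ``slides`` is a sequence of (retained grid, raster) pairs; at least two
    slides are required so negatives span sources. Per-epoch train and
    validation NT-Xent are logged; training early-stops when validation
    loss has not improved for ``patience`` epochs and the best-validation
    weights are restored.
    """
    if len(slides) < 2:
        raise ValueError("need at least 2 slides so negatives exist across sources")
    root = np.random.SeedSequence(schedule.seed)
    init_seed, sample_seed, split_seed, epoch_entropy = (
        int(s) for s in root.generate_state(4) % (2 ** 31))
    if encoder is None:
        encoder = spec.build(np.random.default_rng(init_seed))
    log: dict = {"train_loss": [], "val_loss": []}
    if schedule.epochs == 0:
        return encoder, log

    pool: list[tuple[int, TileRecord]] = []
    for si, (grid, _) in enumerate(slides):
        for rec in sample_tiles(grid, schedule.tiles_per_slide, seed=sample_seed + si):
            pool.append((si, rec))
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(pool))
    n_val = max(2, int(round(schedule.val_fraction * len(pool))))
    val_items = [pool[i] for i in order[:n_val]]
    train_items = [pool[i] for i in order[n_val:]]
    if len(train_items) < 2:
        raise ValueError("too few tiles to form a contrastive batch")

    optimizer = Adam(encoder.parameters(), lr=schedule.lr)
    best_val, best_state, stale = np.inf, None, 0

    def pairs_loss(items, pair_policy, seed_base, epoch_tag):
        feats1, feats2 = [], []
        for j, (si, rec) in enumerate(items):
            grid, raster = slides[si]
            pair = make_positive_pair(rec, grid, pair_policy, raster,
                                      seed=(seed_base + 977 * epoch_tag + j) % (2 ** 31))
            feats1.append(pair.view1)
            feats2.append(pair.view2)
        feats = encoder.preprocess(np.stack(feats1 + feats2))
        z = encoder.project(encoder.embed(Tensor(feats)))
        return nt_xent_from_tensor(z, pair_index_for_stacked_views(len(items)),
                                   schedule.temperature)

    def batch_loss(items, seed_base, epoch_tag):
        if policy.use_neighbor and policy.three_view:
            ssl_policy = replace(policy, use_neighbor=False)
            return (pairs_loss(items, ssl_policy, seed_base, epoch_tag)
                    + pairs_loss(items, policy, seed_base + 1, epoch_tag)) * 0.5
        return pairs_loss(items, policy, seed_base, epoch_tag)

    for epoch in range(schedule.epochs):
        erng = np.random.default_rng((epoch_entropy + epoch) % (2 ** 31))
        order = erng.permutation(len(train_items))
        losses = []
        for start in range(0, len(order), schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            if len(idx) < 2:
                continue
            loss = batch_loss([train_items[i] for i in idx],
                              seed_base=int(erng.integers(0, 2 ** 30)), epoch_tag=epoch)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        # validation pairs use a fixed seed so checkpoint selection is stable
        val = batch_loss(val_items, seed_base=12345, epoch_tag=0).item()
        log["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        log["val_loss"].append(val)
        if val < best_val - 1e-12:
            best_val, best_state, stale = val, copy.deepcopy(encoder.state_dict()), 0
        else:
            stale += 1
            if stale >= schedule.patience:
                break
    if best_state is not None:
        encoder.load_state_dict(best_state)
    return encoder, log


def embed_slide(grid: TileGrid, encoder: TileEncoder,
                raster: np.ndarray) -> Bag:
    """Embed every retained tile of a slide (pre-projection h vectors).

    Instance order follows the manifest order (row-major over the grid).
    """
    ordered = sorted(grid.records, key=lambda r: (r.row, r.col))
    if not ordered:
        warnings.warn(f"slide {grid.slide_id}: empty grid, empty bag returned")
        return Bag(slide_id=grid.slide_id,
                   instances=np.zeros((0, encoder.spec.embedding_dim)))
    tiles = np.stack([extract_tile(raster, rec) for rec in ordered])
    return Bag(slide_id=grid.slide_id, instances=encoder.embed_tiles(tiles))
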