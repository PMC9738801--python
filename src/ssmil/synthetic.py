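"""Synthetic data with the statistical structure contrastive MIL assumes.

Two generators:

* :func:`generate_bags` — embedding-space bags. Each slide's instances are
  drawn from a mixture of *shared* Gaussian clusters (microanatomies common
  to every slide: stroma, normal epithelium, ...) and *class-unique*
  clusters (the discriminative microanatomy, e.g. a tumor subtype pattern),
  with an optional per-slide jitter of the unique-cluster means emulating
  patient-level morphological variation. Cluster means sit on scaled
  coordinate axes of the embedding space; within-cluster noise is isotropic
  Gaussian, so ``effect_size`` (distance between unique-cluster means over
  within-cluster sd) has an exact meaning.

* :func:`generate_slide_image` — small procedural RGB rasters on a tile
  grid, where tiles share per-cluster texture parameters (base color +
  band-limited noise). These exercise tessellation, tissue masking,
  neighbor lookup and tile-level contrastive pretraining without any
  whole-slide image download.

For regression the slide-level target is the *realized* fraction of
instances drawn from the designated signal cluster — a proliferation-score
surrogate at the level synthetic data can honestly test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .attention import Bag

__all__ = [
    "SyntheticBagConfig", "generate_bags",
    "SyntheticImageConfig", "SyntheticSlideImage", "generate_slide_image",
    "write_bags", "read_bags", "write_manifest", "write_slide_image",
]


@dataclass
class SyntheticBagConfig:
    n_slides: int = 200
    instances_per_slide: int = 250
    embed_dim: int = 32
    n_shared_clusters: int = 8
    n_unique_clusters_per_class: int = 2
    n_classes: int = 2
    unique_fraction: float = 0.2
    effect_size: float = 4.0
    noise_sd: float = 1.0
    slide_jitter_sd: float = 0.5
    task: str = "classification"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_slides, self.instances_per_slide, self.embed_dim,
               self.n_unique_clusters_per_class) <= 0:
            raise ValueError("n_slides, instances_per_slide, embed_dim and "
                             "n_unique_clusters_per_class must be positive")
        if self.n_shared_clusters < 0:
            raise ValueError("n_shared_clusters must be non-negative")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 0.0 <= self.unique_fraction <= 1.0:
            raise ValueError("unique_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        n_unique_total = (self.n_classes if self.task == "classification" else 1) \
            * self.n_unique_clusters_per_class
        if self.embed_dim < self.n_shared_clusters + n_unique_total:
            raise ValueError("embed_dim too small to place all cluster means "
                             "on distinct coordinate axes")


def _cluster_means(config: SyntheticBagConfig) -> tuple[np.ndarray, np.ndarray]:
    """Shared means (S, D) and unique means (n_groups, U, D) on scaled axes."""
    d = config.effect_size * config.noise_sd
    dim = config.embed_dim
    s = config.n_shared_clusters
    shared = np.zeros((s, dim))
    for j in range(s):
        shared[j, j] = d
    n_groups = config.n_classes if config.task == "classification" else 1
    u = config.n_unique_clusters_per_class
    unique = np.zeros((n_groups, u, dim))
    # distinct axes per (group, cluster); coefficient d/sqrt(2) makes the
    # distance between any two unique-cluster means exactly d = effect * sd
    for c in range(n_groups):
        for k in range(u):
            unique[c, k, s + c * u + k] = d / np.sqrt(2.0)
    return shared, unique


def generate_bags(config: SyntheticBagConfig) -> list[Bag]:
    """Generate ``config.n_slides`` bags with labels attached.

    Cluster ids recorded per instance: ``0..S-1`` shared, ``>= S`` unique
    (id ``S + class*U + u``), ``-1`` the zero-mean filler used only when
    there are no shared clusters.
    """
    rng = np.random.default_rng(config.seed)
    shared, unique = _cluster_means(config)
    s = config.n_shared_clusters
    u = config.n_unique_clusters_per_class
    k_total = config.instances_per_slide
    dim = config.embed_dim

    if config.task == "classification":
        classes = np.array([i % config.n_classes for i in range(config.n_slides)])
        classes = classes[rng.permutation(config.n_slides)]
    else:
        classes = np.zeros(config.n_slides, dtype=int)

    bags: list[Bag] = []
    for i in range(config.n_slides):
        c = classes[i]
        if config.task == "classification":
            n_unique = int(round(config.unique_fraction * k_total))
        else:
            f = rng.uniform(0.0, config.unique_fraction)
            n_unique = int(round(f * k_total))
        # slide-level jitter of the unique microanatomy means
        jitter = rng.normal(0.0, config.slide_jitter_sd, size=(u, dim)) \
            if config.slide_jitter_sd > 0 else np.zeros((u, dim))
        slide_unique_means = unique[c] + jitter

        clusters = np.empty(k_total, dtype=int)
        means = np.empty((k_total, dim))
        uq_choice = rng.integers(0, u, size=n_unique)
        clusters[:n_unique] = s + c * u + uq_choice
        means[:n_unique] = slide_unique_means[uq_choice]
        n_shared_inst = k_total - n_unique
        if s > 0:
            sh_choice = rng.integers(0, s, size=n_shared_inst)
            clusters[n_unique:] = sh_choice
            means[n_unique:] = shared[sh_choice]
        else:
            clusters[n_unique:] = -1
            means[n_unique:] = 0.0

        instances = means + rng.normal(0.0, config.noise_sd, size=(k_total, dim))
        order = rng.permutation(k_total)
        label: float | int
        if config.task == "classification":
            label = int(c)
        else:
            label = n_unique / k_total  # realized signal fraction
        bags.append(Bag(slide_id=f"slide_{i:04d}", instances=instances[order],
                        label=label, instance_clusters=clusters[order]))
    return bags


# --------------------------------------------------------------------- images

@dataclass
class SyntheticImageConfig:
    grid_rows: int = 8
    grid_cols: int = 8
    tile_size: int = 32
    n_clusters: int = 2
    layout: str = "split"            # single | split | random
    background: str = "none"         # none | random | right
    background_fraction: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.layout not in ("single", "split", "random"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.background not in ("none", "random", "right"):
            raise ValueError(f"unknown background mode {self.background!r}")


@dataclass
class SyntheticSlideImage:
    """Procedural RGB raster whose tessellation recovers ``cluster_map``."""

    pixels: np.ndarray                     # (H, W, 3) uint8
    grid_rows: int
    grid_cols: int
    tile_size: int
    cluster_map: np.ndarray = field(repr=False)  # (rows, cols), -1 = background

    def tile(self, row: int, col: int) -> np.ndarray:
        t = self.tile_size
        return self.pixels[row * t:(row + 1) * t, col * t:(col + 1) * t]


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _cluster_texture(rng: np.random.Generator, cluster: int):
    """Per-cluster texture parameters: base color + noise band settings."""
    base = _hsv_to_rgb((0.13 + 0.61 * cluster) % 1.0, 0.55, 0.72)
    base = np.clip(base + rng.normal(0, 0.02, 3), 0, 1)
    coarse = int(rng.integers(4, 9))         # band-limited noise block size
    amp = 0.08 + 0.04 * rng.random()
    return base, coarse, amp


def generate_slide_image(config: SyntheticImageConfig) -> SyntheticSlideImage:
    rng = np.random.default_rng(config.seed)
    r, c, t = config.grid_rows, config.grid_cols, config.tile_size

    if config.layout == "single":
        cmap = np.zeros((r, c), dtype=int)
    elif config.layout == "split":
        cols = np.minimum((np.arange(c) * config.n_clusters) // c,
                          config.n_clusters - 1)
        cmap = np.tile(cols, (r, 1)).astype(int)
    else:  # random
        cmap = rng.integers(0, config.n_clusters, size=(r, c))

    if config.background != "none" and config.background_fraction > 0:
        n_bg = int(round(config.background_fraction * r * c))
        if config.background == "right":
            flat_order = np.argsort(-np.tile(np.arange(c), r), kind="stable")
            bg_idx = flat_order[:n_bg]
        else:
            bg_idx = rng.choice(r * c, size=n_bg, replace=False)
        cmap.flat[bg_idx] = -1

    textures = {k: _cluster_texture(rng, k) for k in range(config.n_clusters)}
    pixels = np.ones((r * t, c * t, 3))
    for i in range(r):
        for j in range(c):
            k = cmap[i, j]
            if k < 0:
                continue  # background stays white
            base, coarse, amp = textures[k]
            n_blocks = max(1, t // coarse)
            low = rng.normal(0, amp, size=(n_blocks, n_blocks, 3))
            low = np.kron(low, np.ones((coarse, coarse, 1)))[:t, :t]
            if low.shape[0] < t or low.shape[1] < t:
                low = np.pad(low, ((0, t - low.shape[0]), (0, t - low.shape[1]), (0, 0)),
                             mode="edge")
            fine = rng.normal(0, config.noise_sd, size=(t, t, 3))
            pixels[i * t:(i + 1) * t, j * t:(j + 1) * t] = np.clip(
                base + low + fine, 0, 1)
    return SyntheticSlideImage(
        pixels=(pixels * 255).round().astype(np.uint8),
        grid_rows=r, grid_cols=c, tile_size=t, cluster_map=cmap,
    )


# ------------------------------------------------------------------------ I/O

def write_bags(path: str | Path, bags: list[Bag]) -> None:
    """Write bags to the HDF5 embedding container shared by the pipeline."""
    with h5py.File(path, "w") as f:
        for bag in bags:
            grp = f.create_group(bag.slide_id)
            grp.create_dataset("embeddings", data=bag.instances)
            if bag.instance_clusters is not None:
                grp.create_dataset("clusters", data=bag.instance_clusters)
            if bag.label is not None:
                grp.attrs["label"] = bag.label


def read_bags(path: str | Path) -> list[Bag]:
    bags = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f):
            grp = f[slide_id]
            label = grp.attrs.get("label")
            if label is not None and hasattr(label, "item"):
                label = label.item()
            clusters = grp["clusters"][:] if "clusters" in grp else None
            bags.append(Bag(slide_id=slide_id, instances=grp["embeddings"][:],
                            label=label, instance_clusters=clusters))
    return bags


def write_manifest(path: str | Path, bags: list[Bag],
                   data_path: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "slide_id": [b.slide_id for b in bags],
        "label": [b.label for b in bags],
        "path": [data_path or "" for _ in bags],
    })
    df.to_csv(path, index=False)
    return df


def write_slide_image(path: str | Path, image: SyntheticSlideImage) -> None:
    import tifffile

    tifffile.imwrite(path, image.pixels)
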