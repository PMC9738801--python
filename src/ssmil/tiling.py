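"""Whole-slide tessellation, tissue masking and neighbor indexing.

Slides are cut into non-overlapping ``tile_size`` squares at a working
magnification (20x by convention), partial edge tiles dropped. Coordinates
are 0-based, half-open, tile origin at the top-left, so

    x = col * tile_size,   y = row * tile_size

is a bijection between grid and pixel coordinates. Background is masked by
Otsu thresholding the saturation channel of a thumbnail — the dominant
convention in the MIL literature — and a tile is retained when its tissue
fraction reaches the threshold (default 0.5). Neighborhood is Chebyshev
distance 1 on the retained grid (8-connectivity by default, 4 available),
matching the "within one step of the anchor tile" notion used by
neighbor-as-augmentation pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TileRecord", "TileGrid", "tessellate", "tissue_mask", "neighbors",
           "sample_tiles", "extract_tile", "saturation_tissue_mask"]

DEFAULT_MAGNIFICATION = 20.0


@dataclass(frozen=True)
class TileRecord:
    slide_id: str
    row: int
    col: int
    tile_size: int
    magnification: float = DEFAULT_MAGNIFICATION
    tissue_fraction: float = 1.0

    def __post_init__(self):
        if self.row < 0 or self.col < 0:
            raise ValueError("grid coordinates must be non-negative")

    @property
    def x(self) -> int:
        return self.col * self.tile_size

    @property
    def y(self) -> int:
        return self.row * self.tile_size


@dataclass
class TileGrid:
    slide_id: str
    tile_size: int
    magnification: float = DEFAULT_MAGNIFICATION
    records: list[TileRecord] = field(default_factory=list)

    def __post_init__(self):
        self._index = {(r.row, r.col): r for r in self.records}
        if len(self._index) != len(self.records):
            raise ValueError("duplicate (row, col) in tile grid")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, record: TileRecord) -> bool:
        return self._index.get((record.row, record.col)) == record

    def get(self, row: int, col: int) -> TileRecord | None:
        return self._index.get((row, col))

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"slide_id": r.slide_id, "row": r.row, "col": r.col,
             "x": r.x, "y": r.y, "tile_size": r.tile_size,
             "magnification": r.magnification,
             "tissue_fraction": r.tissue_fraction}
            for r in self.records
        ])

    def write_manifest(self, path: str | Path) -> None:
        self.to_manifest().to_csv(path, index=False)

    @classmethod
    def from_manifest(cls, df: pd.DataFrame) -> "TileGrid":
        if len(df) == 0:
            raise ValueError("empty manifest")
        records = [TileRecord(slide_id=r.slide_id, row=int(r.row), col=int(r.col),
                              tile_size=int(r.tile_size),
                              magnification=float(r.magnification),
                              tissue_fraction=float(r.tissue_fraction))
                   for r in df.itertuples()]
        return cls(slide_id=records[0].slide_id, tile_size=records[0].tile_size,
                   magnification=records[0].magnification, records=records)


def _load_raster(slide: np.ndarray | str | Path) -> np.ndarray:
    if isinstance(slide, (str, Path)):
        import tifffile

        try:
            return np.asarray(tifffile.imread(slide))
        except Exception as exc:  # pragma: no cover - I/O failure path
            raise IOError(f"cannot read slide {slide}: {exc}") from exc
    return np.asarray(slide)


def tessellate(slide: np.ndarray | str | Path, tile_size: int,
               working_magnification: float = DEFAULT_MAGNIFICATION,
               source_magnification: float | None = None,
               slide_id: str = "slide") -> TileGrid:
    """Non-overlapping grid over a slide; partial edge tiles are dropped.

    If ``source_magnification`` differs from the working magnification the
    raster is resampled by their ratio first, so all coordinates are
    expressed at the working magnification.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    raster = _load_raster(slide)
    if source_magnification and source_magnification != working_magnification:
        from skimage.transform import rescale

        factor = working_magnification / source_magnification
        raster = rescale(raster, factor, channel_axis=-1 if raster.ndim == 3 else None,
                         anti_aliasing=factor < 1)
    h, w = raster.shape[:2]
    rows, cols = h // tile_size, w // tile_size
    records = [TileRecord(slide_id=slide_id, row=r, col=c, tile_size=tile_size,
                          magnification=working_magnification)
               for r in range(rows) for c in range(cols)]
    return TileGrid(slide_id=slide_id, tile_size=tile_size,
                    magnification=working_magnification, records=records)


def saturation_tissue_mask(thumbnail: np.ndarray,
                           max_background_saturation: float = 0.2) -> np.ndarray:
    """Boolean tissue mask from Otsu on the HSV saturation channel.

    The Otsu threshold is capped at ``max_background_saturation``: stained
    tissue is well above that saturation, and without the cap Otsu would
    bisect an all-tissue thumbnail (it always finds a split).
    """
    from skimage.color import rgb2hsv
    from skimage.filters import threshold_otsu

    thumb = np.asarray(thumbnail, dtype=np.float64)
    if thumb.max() > 1.0:
        thumb = thumb / 255.0
    sat = rgb2hsv(thumb)[..., 1] if thumb.ndim == 3 else thumb
    if np.ptp(sat) < 1e-6:
        return sat > 0.05  # constant image: white/grey = background
    return sat > min(threshold_otsu(sat), max_background_saturation)


def tissue_mask(grid: TileGrid, thumbnail: np.ndarray,
                threshold: float = 0.5,
                downsample: float | None = None) -> TileGrid:
    """Filter grid records whose tissue fraction falls below ``threshold``.

    ``downsample`` is thumbnail pixels per slide pixel; by default it is
    inferred by assuming the thumbnail spans the full tessellated extent.
    Masking is idempotent, and an empty result is a warning, not an error.
    """
    mask = saturation_tissue_mask(thumbnail)
    if downsample is None:
        n_rows = max(r.row for r in grid.records) + 1 if grid.records else 1
        downsample = mask.shape[0] / (n_rows * grid.tile_size)
    t = grid.tile_size * downsample
    kept = []
    for rec in grid.records:
        r0, r1 = int(round(rec.row * t)), int(round((rec.row + 1) * t))
        c0, c1 = int(round(rec.col * t)), int(round((rec.col + 1) * t))
        window = mask[r0:max(r1, r0 + 1), c0:max(c1, c0 + 1)]
        frac = float(window.mean()) if window.size else 0.0
        if frac >= threshold:
            kept.append(replace(rec, tissue_fraction=frac))
    if not kept:
        import warnings

        warnings.warn(f"no tissue tiles retained for slide {grid.slide_id}")
    return TileGrid(slide_id=grid.slide_id, tile_size=grid.tile_size,
                    magnification=grid.magnification, records=kept)


def neighbors(grid: TileGrid, record: TileRecord,
              connectivity: int = 8) -> list[TileRecord]:
    """Retained records within one grid step of ``record`` (0-8 results)."""
    if record not in grid:
        raise KeyError(f"record ({record.row}, {record.col}) not in grid")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            if connectivity == 4 and abs(dr) + abs(dc) != 1:
                continue
            if dr + record.row < 0 or dc + record.col < 0:
                continue
            rec = grid.get(record.row + dr, record.col + dc)
            if rec is not None:
                out.append(rec)
    return out


def sample_tiles(grid: TileGrid, n: int, seed: int) -> list[TileRecord]:
    """Uniform sample of min(n, |grid|) records without replacement."""
    if len(grid) == 0:
        raise ValueError("cannot sample from an empty grid")
    rng = np.random.default_rng(seed)
    ordered = sorted(grid.records, key=lambda r: (r.row, r.col))
    idx = rng.choice(len(ordered), size=min(n, len(ordered)), replace=False)
    return [ordered[i] for i in sorted(idx)]


def extract_tile(raster: np.ndarray, record: TileRecord) -> np.ndarray:
    """Pixel block of a tile, as float64 in [0, 1]."""
    t = record.tile_size
    tile = np.asarray(raster[record.y:record.y + t, record.x:record.x + t],
                      dtype=np.float64)
    if tile.shape[:2] != (t, t):
        raise ValueError("tile extends past the raster edge")
    if tile.max() > 1.0:
        tile = tile / 255.0
    return tile
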