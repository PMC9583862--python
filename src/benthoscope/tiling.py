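"""Tile slicing, train/validation region splitting, and map reassembly.

The translation network consumes fixed-size square tiles, so a scene is cut
into a non-overlapping floor(H/T) x floor(W/T) grid (residual right/bottom
margins are dropped).  The scene is split into a training and a validation
region along one axis — by default 54% of rows for training, mirroring a
boundary drawn across the depth axis of a bed — with the boundary snapped to
a tile multiple so no tile straddles it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .raster_io import LabelMap, OrthoImage

__all__ = [
    "TilePair",
    "RegionSplit",
    "InvalidSplitError",
    "AssemblyError",
    "slice_tiles",
    "resolve_boundary",
    "split_scene",
    "reassemble",
]

logger = logging.getLogger(__name__)


class InvalidSplitError(ValueError):
    """Raised for degenerate train fractions or non-snappable boundaries."""


class AssemblyError(ValueError):
    """Raised when a tile grid has missing or duplicate cells."""


@dataclass
class TilePair:
    """Co-registered (image tile, label tile) at a grid position.

    ``region`` records which side of the train/validation split the tile
    came from; ``transform`` records a flip applied by augmentation.
    """

    image_tile: OrthoImage
    label_tile: LabelMap
    grid_row: int
    grid_col: int
    region: str = "train"
    transform: str = "none"

    def __post_init__(self):
        ih, iw = self.image_tile.shape
        lh, lw = self.label_tile.shape
        if (ih, iw) != (lh, lw):
            raise ValueError(f"image tile {ih}x{iw} and label tile {lh}x{lw} differ")
        if ih != iw:
            raise ValueError(f"tiles must be square, got {ih}x{iw}")

    @property
    def size(self) -> int:
        return self.image_tile.shape[0]


@dataclass
class RegionSplit:
    """An axis-aligned train/validation split.

    ``boundary_index`` (pixels from the origin along the axis) is resolved
    from ``train_fraction`` at split time: round(fraction x extent) snapped
    to the nearest tile multiple.
    """

    axis: str = "rows"
    train_fraction: float = 0.54
    boundary_index: int | None = None

    def __post_init__(self):
        if self.axis not in ("rows", "cols"):
            raise InvalidSplitError(f"axis must be 'rows' or 'cols', got {self.axis!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidSplitError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def slice_tiles(scene, tile_size: int, region: str = "train") -> list[TilePair]:
    """Cut a scene into non-overlapping square tiles.

    Returns floor(H/T) x floor(W/T) tiles in row-major order; residual
    margins are dropped.  A tile size exceeding the scene returns an empty
    list with a warning.
    """
    if tile_size < 8:
        raise ValueError(f"tile_size must be >= 8, got {tile_size}")
    h, w = scene.image.shape
    t = tile_size
    if t > min(h, w):
        logger.warning("tile size %d exceeds scene extent %dx%d: no tiles", t, h, w)
        return []
    tiles = []
    for gr in range(h // t):
        for gc in range(w // t):
            sl = (slice(gr * t, (gr + 1) * t), slice(gc * t, (gc + 1) * t))
            tiles.append(
                TilePair(
                    OrthoImage(scene.image.pixels[sl].copy(),
                               pixel_size=scene.image.pixel_size),
                    LabelMap(scene.truth.labels[sl].copy()),
                    gr, gc, region=region,
                )
            )
    return tiles


def resolve_boundary(extent: int, train_fraction: float, tile_size: int) -> int:
    """round(fraction x extent) snapped to the nearest tile multiple."""
    raw = round(train_fraction * extent)
    snapped = int(round(raw / tile_size)) * tile_size
    if snapped <= 0 or snapped >= extent:
        raise InvalidSplitError(
            f"boundary {snapped} degenerate for extent {extent} "
            f"(fraction {train_fraction}, tile {tile_size})"
        )
    return snapped


def split_scene(scene, split: RegionSplit, tile_size: int):
    """Partition a scene into (train, validation) sub-scenes.

    The two regions tile the full scene exactly; the boundary lies on a
    tile multiple so no tile straddles it.  Returns new ScenePairs viewing
    copies of the parent arrays, plus the resolved split.
    """
    from .scene_sim import ScenePair  # deferred: avoid import cycle

    h, w = scene.image.shape
    extent = h if split.axis == "rows" else w
    b = resolve_boundary(extent, split.train_fraction, tile_size)
    resolved = replace(split, boundary_index=b)

    def sub(sl):
        if split.axis == "rows":
            px, lb = scene.image.pixels[sl], scene.truth.labels[sl]
        else:
            px, lb = scene.image.pixels[:, sl], scene.truth.labels[:, sl]
        cfg = scene.config
        return ScenePair(
            OrthoImage(px.copy(), pixel_size=scene.image.pixel_size),
            LabelMap(lb.copy()),
            cfg,
        )

    train = sub(slice(0, b))
    valid = sub(slice(b, extent))
    return train, valid, resolved


def reassemble(tiles, grid_shape: tuple[int, int]) -> LabelMap:
    """Stitch translated label tiles back into one map.

    ``tiles`` is a list of (grid_row, grid_col, LabelMap) triples or of
    TilePairs (whose label tile is used).  Every grid cell must be present
    exactly once.
    """
    rows, cols = grid_shape
    entries = {}
    t = None
    for item in tiles:
        if isinstance(item, TilePair):
            gr, gc, lab = item.grid_row, item.grid_col, item.label_tile
        else:
            gr, gc, lab = item
        if (gr, gc) in entries:
            raise AssemblyError(f"duplicate grid cell ({gr}, {gc})")
        entries[(gr, gc)] = lab
        t = lab.shape[0]
    for gr in range(rows):
        for gc in range(cols):
            if (gr, gc) not in entries:
                raise AssemblyError(f"missing grid cell ({gr}, {gc})")
    if len(entries) != rows * cols:
        extra = set(entries) - {(r, c) for r in range(rows) for c in range(cols)}
        raise AssemblyError(f"grid cells outside {grid_shape}: {sorted(extra)}")
    out = np.empty((rows * t, cols * t), dtype=np.uint8)
    for (gr, gc), lab in entries.items():
        out[gr * t:(gr + 1) * t, gc * t:(gc + 1) * t] = lab.labels
    return LabelMap(out)
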