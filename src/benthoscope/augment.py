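"""Flip augmentation of cGAN training tiles.

Training data are expanded exactly four-fold: to the originals are added
horizontal, vertical, and simultaneous horizontal+vertical flipped copies,
image and label tile transformed together.  No rotations, crops or color
jitter — flips only, applied after the train/validation split and only to
training tiles.
"""

from __future__ import annotations

import numpy as np

from .raster_io import LabelMap, OrthoImage
from .tiling import TilePair

__all__ = ["FLIP_TRANSFORMS", "apply_flip", "flip_tile", "flip_augment"]

#: fixed output order: originals first, then h, v, hv variants
FLIP_TRANSFORMS = ("none", "h", "v", "hv")


def apply_flip(arr: np.ndarray, transform: str) -> np.ndarray:
    """Apply a named flip to a 2-D or 3-D (H, W[, C]) array."""
    if transform == "none":
        return arr.copy()
    if transform == "h":
        return arr[:, ::-1].copy()
    if transform == "v":
        return arr[::-1, :].copy()
    if transform == "hv":
        return arr[::-1, ::-1].copy()
    raise ValueError(f"unknown flip transform {transform!r}")


def flip_tile(tile: TilePair, transform: str) -> TilePair:
    """Flip image and label tile with the same transform."""
    return TilePair(
        OrthoImage(apply_flip(tile.image_tile.pixels, transform),
                   pixel_size=tile.image_tile.pixel_size),
        LabelMap(apply_flip(tile.label_tile.labels, transform)),
        tile.grid_row, tile.grid_col,
        region=tile.region, transform=transform,
    )


def flip_augment(tiles: list[TilePair]) -> list[TilePair]:
    """Quadruple a tile list by adding h, v, and hv flipped copies.

    Output order is fixed: all originals, then all horizontal flips, then
    vertical, then both — so 980 training tiles become 3920.
    """
    out: list[TilePair] = []
    for transform in FLIP_TRANSFORMS:
        out.extend(flip_tile(t, transform) for t in tiles)
    return out
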