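"""Mode-collapse mitigation: posterize dominant-class tiles into subclasses.

When most training targets are covered by a single class (here ZM, the
dominant eelgrass), the adversarial training data become nearly uniform and
the generator collapses onto one output.  The fix re-labels ZM-only training
tiles into brightness-derived subclasses: the tile's luminance
(0.299 R + 0.587 G + 0.114 B) is posterized to ``n_subclasses`` levels and
each pixel receives the subclass of its level (ZM1 darkest .. ZM3 brightest).
Subclasses exist only in training targets and are merged back to ZM after
translation.

Posterization is computed by *exact* 1-D k-means: a dynamic program over the
at most 256 discrete luminance levels finds the globally optimal contiguous
partition (weighted sum of squared deviations), which is deterministic and
reproducible — Lloyd iterations from heuristic starts can stall in local
optima.  Quantization is per tile by default; a ``global`` mode pools the
luminance histogram over all monoclass tiles first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import SUBCLASSES, LabelMap, label_index
from .tiling import TilePair

__all__ = [
    "PosterizeConfig",
    "PreconditionError",
    "luminance",
    "optimal_1d_kmeans",
    "is_monoclass",
    "posterize_subclasses",
    "fit_global_breaks",
    "posterize_training_tiles",
]


class PreconditionError(ValueError):
    """Raised when posterization is applied to an ineligible tile."""


@dataclass
class PosterizeConfig:
    """Which class to subdivide, into how many levels, and when.

    A tile is eligible when at least ``monoclass_threshold`` of its pixels
    carry ``target_class`` (default 1.0: strictly single-class tiles).
    ``mode`` selects per-tile or pooled (global) luminance quantization.
    """

    target_class: str = "ZM"
    n_subclasses: int = 3
    monoclass_threshold: float = 1.0
    mode: str = "per_tile"

    def __post_init__(self):
        if not 2 <= self.n_subclasses <= len(SUBCLASSES):
            raise ValueError(
                f"n_subclasses must be in [2, {len(SUBCLASSES)}], got {self.n_subclasses}"
            )
        if not 0.0 < self.monoclass_threshold <= 1.0:
            raise ValueError("monoclass_threshold must be in (0, 1]")
        if self.mode not in ("per_tile", "global"):
            raise ValueError(f"mode must be 'per_tile' or 'global', got {self.mode!r}")


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Integer luminance 0..255 of an (H, W, 3) uint8 image."""
    px = pixels.astype(np.float64)
    lum = 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]
    return np.clip(np.rint(lum), 0, 255).astype(np.int64)


def optimal_1d_kmeans(
    values: np.ndarray, weights: np.ndarray, k: int
) -> list[np.ndarray]:
    """Globally optimal weighted 1-D k-means on sorted distinct values.

    Dynamic program over contiguous partitions minimizing the weighted sum
    of squared deviations; O(k L^2) for L distinct values.  Returns the list
    of clusters as index arrays into ``values`` (ascending).  With fewer
    distinct values than k, each value is its own cluster.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    L = len(v)
    if L <= k:
        return [order[[i]] for i in range(L)]

    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwv = np.concatenate([[0.0], np.cumsum(w * v)])
    cwv2 = np.concatenate([[0.0], np.cumsum(w * v * v)])

    def cost(i: int, j: int) -> float:  # inclusive segment [i, j]
        W = cw[j + 1] - cw[i]
        S = cwv[j + 1] - cwv[i]
        S2 = cwv2[j + 1] - cwv2[i]
        return S2 - S * S / W if W > 0 else 0.0

    D = np.full((k + 1, L), np.inf)
    back = np.zeros((k + 1, L), dtype=np.int64)
    for j in range(L):
        D[1, j] = cost(0, j)
    for m in range(2, k + 1):
        for j in range(m - 1, L):
            for i in range(m - 1, j + 1):
                c = D[m - 1, i - 1] + cost(i, j)
                if c < D[m, j]:
                    D[m, j] = c
                    back[m, j] = i
    clusters: list[np.ndarray] = []
    j = L - 1
    for m in range(k, 0, -1):
        i = back[m, j] if m > 1 else 0
        clusters.append(order[i:j + 1])
        j = i - 1
    clusters.reverse()
    return clusters


def is_monoclass(tile: TilePair, cls: str, threshold: float = 1.0) -> bool:
    """True iff at least ``threshold`` of tile pixels carry class ``cls``."""
    frac = float((tile.label_tile.labels == label_index(cls)).mean())
    return frac >= threshold


def _breaks_from_levels(levels: np.ndarray, counts: np.ndarray, k: int) -> np.ndarray:
    """Upper luminance bound of each cluster (ascending), last = 255."""
    clusters = optimal_1d_kmeans(levels.astype(np.float64), counts.astype(np.float64), k)
    uppers = [int(levels[c].max()) for c in clusters]
    uppers[-1] = 255
    return np.asarray(uppers)


def posterize_subclasses(
    tile: TilePair, config: PosterizeConfig, breaks: np.ndarray | None = None
) -> TilePair:
    """Re-label an eligible tile's target-class pixels into subclasses.

    ``breaks`` (ascending upper luminance bounds, one per subclass) may be
    supplied for global mode; otherwise they are fitted on this tile's own
    luminance histogram.  The image tile is unchanged — posterization
    redefines the *ground truth*, not the photograph.  Non-target pixels
    (possible when the monoclass threshold is below 1) keep their labels.
    """
    if tile.region == "validation":
        raise PreconditionError("posterization is forbidden on validation tiles")
    if not is_monoclass(tile, config.target_class, config.monoclass_threshold):
        raise PreconditionError(
            f"tile ({tile.grid_row}, {tile.grid_col}) is not "
            f"{config.target_class}-monoclass at threshold {config.monoclass_threshold}"
        )
    target_idx = label_index(config.target_class)
    mask = tile.label_tile.labels == target_idx
    lum = luminance(tile.image_tile.pixels)
    if breaks is None:
        levels, counts = np.unique(lum[mask], return_counts=True)
        breaks = _breaks_from_levels(levels, counts, config.n_subclasses)
    sub_of_lum = np.searchsorted(breaks, np.arange(256))
    sub_of_lum = np.minimum(sub_of_lum, len(breaks) - 1)
    sub_idx = np.array([label_index(s) for s in SUBCLASSES], dtype=np.uint8)
    new_labels = tile.label_tile.labels.copy()
    new_labels[mask] = sub_idx[sub_of_lum[lum[mask]]]
    return TilePair(
        tile.image_tile, LabelMap(new_labels), tile.grid_row, tile.grid_col,
        region=tile.region, transform=tile.transform,
    )


def fit_global_breaks(tiles: list[TilePair], config: PosterizeConfig) -> np.ndarray:
    """Pooled luminance breaks over all eligible tiles (global mode)."""
    hist = np.zeros(256, dtype=np.int64)
    for t in tiles:
        if not is_monoclass(t, config.target_class, config.monoclass_threshold):
            continue
        mask = t.label_tile.labels == label_index(config.target_class)
        hist += np.bincount(luminance(t.image_tile.pixels)[mask], minlength=256)
    if hist.sum() == 0:
        raise PreconditionError("no eligible monoclass tiles to fit global breaks")
    levels = np.nonzero(hist)[0]
    return _breaks_from_levels(levels, hist[levels], config.n_subclasses)


def posterize_training_tiles(
    tiles: list[TilePair], config: PosterizeConfig | None = None
) -> list[TilePair]:
    """Posterize every eligible monoclass training tile, pass others through."""
    config = config or PosterizeConfig()
    breaks = None
    if config.mode == "global":
        breaks = fit_global_breaks(tiles, config)
    out = []
    for t in tiles:
        if t.region != "validation" and is_monoclass(
            t, config.target_class, config.monoclass_threshold
        ):
            out.append(posterize_subclasses(t, config, breaks))
        else:
            out.append(t)
    return out
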