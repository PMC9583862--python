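"""Posterization into brightness subclasses, checked against brute force."""

import itertools

import numpy as np
import pytest

from benthoscope.raster_io import SUBCLASSES, label_index, merge_subclasses
from benthoscope.subclass import (
    PosterizeConfig,
    PreconditionError,
    is_monoclass,
    luminance,
    optimal_1d_kmeans,
    posterize_subclasses,
    posterize_training_tiles,
)
from conftest import make_tile

ZM = label_index("ZM")
NV = label_index("NV")


def _zm_tile(image, region="train"):
    return make_tile(image, np.full(image.shape[:2], ZM, dtype=np.uint8),
                     region=region)


def brute_force_1d_kmeans(values, weights, k):
    """Enumerate all contiguous partitions of sorted values; minimal SSE."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    L = len(v)
    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, L), k - 1):
        bounds = (0, *cuts, L)
        cost = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_v, seg_w = v[a:b], w[a:b]
            mu = (seg_v * seg_w).sum() / seg_w.sum()
            cost += (seg_w * (seg_v - mu) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, bounds
    return best, best_cost


class TestMonoclass:
    def test_pure_tile_is_monoclass(self):
        t = _zm_tile(np.zeros((10, 10, 3), dtype=np.uint8))
        assert is_monoclass(t, "ZM", 1.0)

    def test_one_percent_contamination_fails_strict_threshold(self):
        lab = np.full((10, 10), ZM, dtype=np.uint8)
        lab[0, 0] = NV
        t = make_tile(np.zeros((10, 10, 3), dtype=np.uint8), lab)
        assert not is_monoclass(t, "ZM", 1.0)
        assert is_monoclass(t, "ZM", 0.95)


class TestOptimal1dKmeans:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        r = np.random.default_rng(seed)
        L = int(r.integers(4, 12))
        values = np.sort(r.choice(256, L, replace=False)).astype(float)
        weights = r.integers(1, 50, L).astype(float)
        k = int(r.integers(2, 4))
        clusters = optimal_1d_kmeans(values, weights, k)
        # reconstruct DP cost
        cost_dp = 0.0
        for c in clusters:
            seg_v, seg_w = values[c], weights[c]
            mu = (seg_v * seg_w).sum() / seg_w.sum()
            cost_dp += (seg_w * (seg_v - mu) ** 2).sum()
        _, cost_bf = brute_force_1d_kmeans(values, weights, k)
        assert cost_dp == pytest.approx(cost_bf, rel=1e-9, abs=1e-9)

    def test_fewer_values_than_clusters(self):
        clusters = optimal_1d_kmeans(np.array([3.0, 9.0]), np.array([1.0, 1.0]), 3)
        assert len(clusters) == 2


class TestPosterize:
    def test_three_distinct_colors_lossless(self):
        # a tile with exactly 3 colors quantizes pixel-for-pixel
        img = np.zeros((9, 9, 3), dtype=np.uint8)
        img[:3] = (20, 30, 20)
        img[3:6] = (90, 110, 90)
        img[6:] = (200, 220, 200)
        out = posterize_subclasses(_zm_tile(img), PosterizeConfig())
        lab = out.label_tile.labels
        assert (lab[:3] == label_index("ZM1")).all()
        assert (lab[3:6] == label_index("ZM2")).all()
        assert (lab[6:] == label_index("ZM3")).all()

    def test_uniform_tile_single_subclass(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        out = posterize_subclasses(_zm_tile(img), PosterizeConfig())
        assert len(np.unique(out.label_tile.labels)) == 1

    def test_gradient_bands_match_exhaustive_oracle(self):
        """Smooth dark-to-bright gradient: bands equal the optimal 1-D
        3-quantization of the luminance values (exhaustive oracle)."""
        ramp = np.linspace(10, 240, 24).astype(np.uint8)
        img = np.repeat(ramp[:, None], 24, axis=1)[..., None].repeat(3, axis=-1)
        tile = _zm_tile(img)
        out = posterize_subclasses(tile, PosterizeConfig())
        lum = luminance(img)
        levels, counts = np.unique(lum, return_counts=True)
        bounds, _ = brute_force_1d_kmeans(levels.astype(float), counts.astype(float), 3)
        # oracle band upper edges -> expected subclass per level
        expected = np.zeros(len(levels), dtype=int)
        for band, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            expected[a:b] = band
        level_of = {lv: e for lv, e in zip(levels, expected)}
        sub_idx = {label_index(s): i for i, s in enumerate(SUBCLASSES)}
        got = np.vectorize(lambda x: sub_idx[x])(out.label_tile.labels)
        want = np.vectorize(lambda x: level_of[x])(lum)
        np.testing.assert_array_equal(got, want)

    def test_non_monoclass_tile_rejected(self):
        lab = np.full((8, 8), ZM, dtype=np.uint8)
        lab[0, 0] = NV
        t = make_tile(np.zeros((8, 8, 3), dtype=np.uint8), lab)
        with pytest.raises(PreconditionError, match="monoclass"):
            posterize_subclasses(t, PosterizeConfig())

    def test_validation_tile_rejected(self):
        t = _zm_tile(np.zeros((8, 8, 3), dtype=np.uint8), region="validation")
        with pytest.raises(PreconditionError, match="validation"):
            posterize_subclasses(t, PosterizeConfig())

    def test_merge_restores_zm_support(self, rng):
        """Support preservation: posterize then merge is the identity on labels."""
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        tile = _zm_tile(img)
        out = posterize_subclasses(tile, PosterizeConfig())
        assert set(out.label_tile.codes_present()) <= set(SUBCLASSES)
        assert len(np.unique(out.label_tile.labels)) <= 3
        merged = merge_subclasses(out.label_tile)
        np.testing.assert_array_equal(merged.labels, tile.label_tile.labels)

    def test_partial_tile_keeps_other_labels(self):
        lab = np.full((10, 10), ZM, dtype=np.uint8)
        lab[9] = NV  # 10% non-target
        img = np.random.default_rng(0).integers(0, 256, (10, 10, 3), dtype=np.uint8)
        t = make_tile(img, lab)
        out = posterize_subclasses(t, PosterizeConfig(monoclass_threshold=0.9))
        assert (out.label_tile.labels[9] == NV).all()
        assert set(np.unique(out.label_tile.labels[:9])) <= {
            label_index(s) for s in SUBCLASSES
        }


class TestPosterizeTrainingTiles:
    def test_only_monoclass_tiles_changed(self, rng):
        imgs = rng.integers(0, 256, (3, 8, 8, 3), dtype=np.uint8)
        mono = _zm_tile(imgs[0])
        mixed_lab = np.full((8, 8), ZM, dtype=np.uint8)
        mixed_lab[0] = NV
        mixed = make_tile(imgs[1], mixed_lab)
        out = posterize_training_tiles([mono, mixed])
        assert set(out[0].label_tile.codes_present()) <= set(SUBCLASSES)
        np.testing.assert_array_equal(out[1].label_tile.labels, mixed_lab)

    def test_global_mode_shares_breaks(self, rng):
        dark = _zm_tile(np.full((8, 8, 3), 30, dtype=np.uint8))
        bright = _zm_tile(np.full((8, 8, 3), 220, dtype=np.uint8))
        mid = _zm_tile(np.full((8, 8, 3), 120, dtype=np.uint8))
        out = posterize_training_tiles(
            [dark, mid, bright], PosterizeConfig(mode="global")
        )
        subs = [np.unique(t.label_tile.labels)[0] for t in out]
        assert subs == [label_index("ZM1"), label_index("ZM2"), label_index("ZM3")]
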