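"""Baselines: segmentation contracts, object features, SVM behavior."""

import numpy as np
import pytest

from benthoscope.conventional import (
    SegmentationParams,
    compute_object_features,
    object_svm_fit,
    pixel_svm_fit,
    predict_object_map,
    predict_pixel_map,
    sample_training_polygons,
    segment,
    TrainingPolygons,
)
from benthoscope.raster_io import LabelMap, OrthoImage, label_index


def _two_halves_image(h=64, w=64):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, : w // 2] = (200, 40, 40)
    img[:, w // 2:] = (40, 40, 200)
    return OrthoImage(img)


class TestSegmentation:
    def test_uniform_image_single_segment(self):
        img = OrthoImage(np.full((40, 40, 3), 120, dtype=np.uint8))
        seg = segment(img, SegmentationParams(20, 5, 50))
        assert seg.max() == 0

    def test_two_homogeneous_halves(self):
        # halves (2048 px) exceed the published min size 500; boundary-blur
        # slivers fall below it and are absorbed
        seg = segment(_two_halves_image(), SegmentationParams(20, 5, 500))
        assert seg.max() == 1
        assert len(np.unique(seg[:, :20])) == 1
        assert len(np.unique(seg[:, 44:])) == 1

    def test_min_segment_size_honored(self, medium_scene):
        # the published parameterization: (20, 5, 500)
        seg = segment(medium_scene.image, SegmentationParams(20, 5, 500))
        sizes = np.bincount(seg.ravel())
        assert sizes.min() >= 500

    def test_partition_property(self, medium_scene):
        seg = segment(medium_scene.image, SegmentationParams(20, 5, 500))
        assert seg.shape == medium_scene.image.shape
        ids = np.unique(seg)
        np.testing.assert_array_equal(ids, np.arange(len(ids)))

    def test_min_size_monotonicity(self, medium_scene):
        """Raising min_segment_size never increases the segment count."""
        counts = []
        for ms in (100, 500, 2000):
            seg = segment(medium_scene.image, SegmentationParams(20, 5, ms))
            counts.append(seg.max() + 1)
        assert counts[0] >= counts[1] >= counts[2]

    def test_spectral_detail_monotonicity(self, medium_scene):
        """Higher spectral detail gives a finer (or equal) segmentation."""
        counts = []
        for sd in (5, 12, 20):
            seg = segment(medium_scene.image, SegmentationParams(sd, 5, 200))
            counts.append(seg.max() + 1)
        assert counts[0] <= counts[1] <= counts[2]

    def test_min_size_exceeding_area_gives_single_segment(self, caplog):
        img = OrthoImage(np.zeros((10, 10, 3), dtype=np.uint8))
        seg = segment(img, SegmentationParams(20, 5, 1000))
        assert seg.max() == 0


class TestObjectFeatures:
    def test_solid_rectangle_rectangularity_one(self):
        img = OrthoImage(np.full((20, 30, 3), 90, dtype=np.uint8))
        mask = np.zeros((20, 30), dtype=bool)
        mask[4:16, 5:25] = True
        f = compute_object_features(img, mask)
        assert f.rectangularity == 1.0
        assert f.pixel_count == 12 * 20

    def test_digital_disk_compactness(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2
        img = OrthoImage(np.full((64, 64, 3), 90, dtype=np.uint8))
        f = compute_object_features(img, mask)
        assert 0.85 <= f.compactness <= 1.0

    def test_uniform_segment_color_stats(self):
        img = OrthoImage(np.full((10, 10, 3), (30, 60, 90), dtype=np.uint8))
        mask = np.ones((10, 10), dtype=bool)
        f = compute_object_features(img, mask)
        assert f.std == (0.0, 0.0, 0.0)
        assert f.converged_color == f.mean_digital_number == (30.0, 60.0, 90.0)

    def test_empty_mask_rejected(self):
        img = OrthoImage(np.zeros((5, 5, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            compute_object_features(img, np.zeros((5, 5), dtype=bool))


class TestPixelSvm:
    def _separable_setup(self):
        img = _two_halves_image()
        polys = TrainingPolygons(
            {"BA": [(5, 5, 15, 15)], "GA": [(5, 45, 15, 55)]}, (64, 64)
        )
        return img, polys

    def test_disjoint_supports_perfect_accuracy(self):
        img, polys = self._separable_setup()
        clf = pixel_svm_fit(img, polys)
        pred = predict_pixel_map(clf, img)
        truth = np.where(
            np.arange(64)[None, :] < 32, label_index("BA"), label_index("GA")
        )
        assert (pred.labels == truth).mean() == 1.0

    def test_duplicated_training_pixels_same_predictions(self, rng):
        img, polys = self._separable_setup()
        doubled = TrainingPolygons(
            {c: r + r for c, r in polys.rectangles.items()}, (64, 64)
        )
        probe = OrthoImage(rng.integers(0, 256, (16, 16, 3), dtype=np.uint8))
        a = predict_pixel_map(pixel_svm_fit(img, polys), probe)
        b = predict_pixel_map(pixel_svm_fit(img, doubled), probe)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_single_class_rejected(self):
        img = _two_halves_image()
        polys = TrainingPolygons({"BA": [(5, 5, 15, 15)]}, (64, 64))
        with pytest.raises(ValueError, match="2 classes"):
            pixel_svm_fit(img, polys)

    def test_prediction_deterministic_and_total(self):
        img, polys = self._separable_setup()
        clf = pixel_svm_fit(img, polys)
        a = predict_pixel_map(clf, img)
        b = predict_pixel_map(clf, img)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.shape == img.shape

    def test_uniform_image_uniform_map(self):
        img, polys = self._separable_setup()
        clf = pixel_svm_fit(img, polys)
        out = predict_pixel_map(clf, OrthoImage(np.full((8, 8, 3), 200, np.uint8)))
        assert len(np.unique(out.labels)) == 1


class TestObjectSvm:
    def test_two_halves_classified(self):
        img = _two_halves_image()
        seg = segment(img, SegmentationParams(20, 5, 500))
        polys = TrainingPolygons(
            {"BA": [(5, 5, 15, 15)], "GA": [(5, 45, 15, 55)]}, (64, 64)
        )
        clf = object_svm_fit(img, seg, polys)
        pred = predict_object_map(clf, img, seg)
        assert (pred.labels[:, :32] == label_index("BA")).all()
        assert (pred.labels[:, 32:] == label_index("GA")).all()

    def test_prediction_piecewise_constant_on_segments(self, medium_scene):
        from scipy import ndimage

        img = medium_scene.image
        seg = segment(img, SegmentationParams(20, 5, 500))
        polys = sample_training_polygons(medium_scene.truth, 3)
        clf = object_svm_fit(img, seg, polys)
        pred = predict_object_map(clf, img, seg)
        for sid in np.unique(seg)[:10]:
            assert len(np.unique(pred.labels[seg == sid])) == 1
        # no salt-and-pepper: component count bounded by segment count
        n_comp = 0
        for cls in np.unique(pred.labels):
            n_comp += ndimage.label(pred.labels == cls)[1]
        assert n_comp <= seg.max() + 1


class TestTrainingPolygons:
    def test_sampled_polygons_are_pure_and_inside(self, medium_scene):
        polys = sample_training_polygons(medium_scene.truth, 0)
        assert len(polys.rectangles) >= 2
        for cls, rects in polys.rectangles.items():
            mask = polys.class_mask(cls)
            assert (medium_scene.truth.labels[mask] == label_index(cls)).all()

    def test_polygon_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            TrainingPolygons({"ZM": [(0, 0, 20, 20)]}, (10, 10))

    def test_imbalance_mimics_field_digitization(self, medium_scene):
        # dominant-class polygons dwarf the rarest class, as in real training sets
        polys = sample_training_polygons(medium_scene.truth, 0)
        areas = polys.areas()
        if "ZM" in areas and "BA" in areas:
            assert areas["ZM"] > 10 * areas["BA"]
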