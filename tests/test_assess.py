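"""Accuracy metrics vs brute-force recounting, agreement labels, CSV dialect."""

import numpy as np
import pytest

from benthoscope.assess import (
    ConfusionMatrix,
    accuracy_report,
    agreement_label,
    confusion,
    kappa,
    load_reference_table,
    overall_accuracy,
    parse_matrix_csv,
    producer_accuracy,
    salt_pepper_fraction,
    sample_points,
    user_accuracy,
    write_matrix_csv,
)
from benthoscope.raster_io import LabelMap, UNLABELED_INDEX, label_index


def brute_force_metrics(cm: ConfusionMatrix):
    """Expand the matrix into labeled point pairs and recount everything."""
    mapped, truth = [], []
    for i, mc in enumerate(cm.classes):
        for j, tc in enumerate(cm.classes):
            mapped += [mc] * int(cm.counts[i, j])
            truth += [tc] * int(cm.counts[i, j])
    n = len(mapped)
    oa = sum(m == t for m, t in zip(mapped, truth)) / n
    pe = sum(
        (sum(m == c for m in mapped) / n) * (sum(t == c for t in truth) / n)
        for c in cm.classes
    )
    k = (oa - pe) / (1 - pe)
    ua = {}
    pa = {}
    for c in cm.classes:
        row = [(m, t) for m, t in zip(mapped, truth) if m == c]
        col = [(m, t) for m, t in zip(mapped, truth) if t == c]
        ua[c] = sum(m == t for m, t in row) / len(row) if row else None
        pa[c] = sum(m == t for m, t in col) / len(col) if col else None
    return oa, k, ua, pa


class TestMetricsOracle:
    @pytest.mark.parametrize("seed", range(100))
    def test_metrics_match_brute_force_on_random_matrices(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 5))
        counts = r.integers(0, 20, (k, k))
        if counts.sum() == 0 or np.trace(counts) == counts.sum():
            counts[0, 1] += 1
        cm = ConfusionMatrix([f"C{i}" for i in range(k)], counts)
        oa, kap, ua, pa = brute_force_metrics(cm)
        assert overall_accuracy(cm) == pytest.approx(oa, abs=1e-12)
        assert kappa(cm) == pytest.approx(kap, abs=1e-9)
        for c in cm.classes:
            for got, want in ((user_accuracy(cm, c), ua[c]),
                              (producer_accuracy(cm, c), pa[c])):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(["A", "B"], np.diag([7, 3]))
        assert overall_accuracy(cm) == 1.0
        assert kappa(cm) == 1.0
        assert user_accuracy(cm, "A") == producer_accuracy(cm, "A") == 1.0

    def test_chance_agreement_kappa_zero(self):
        # rows proportional to column margins: agreement equals chance
        cm = ConfusionMatrix(["A", "B"], np.array([[40, 10], [40, 10]]))
        assert kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_invariant_under_simultaneous_permutation(self, rng):
        counts = rng.integers(0, 30, (4, 4))
        cm = ConfusionMatrix(list("ABCD"), counts)
        perm = rng.permutation(4)
        cm2 = ConfusionMatrix(
            [cm.classes[i] for i in perm], counts[np.ix_(perm, perm)]
        )
        assert kappa(cm) == pytest.approx(kappa(cm2), abs=1e-12)


class TestReferenceTables:
    """The printed matrices reproduce every headline metric at 3 d.p."""

    @pytest.mark.parametrize(
        "key,oa,k",
        [
            ("visual_interpretation", 0.786, 0.687),
            ("pixel", 0.427, 0.178),
            ("object", 0.719, 0.315),
            ("dnn", 0.818, 0.618),
        ],
    )
    def test_oa_and_kappa(self, key, oa, k):
        cm = load_reference_table(key)
        rep = accuracy_report(cm).rounded()
        assert rep["OA"] == oa
        assert rep["K"] == k

    def test_per_class_headlines(self):
        pixel = load_reference_table("pixel")
        rep = accuracy_report(pixel).rounded()
        assert rep["UA"]["ZM"] == 0.781
        assert rep["PA"]["ZM"] == 0.421
        assert rep["PA"]["BA"] == 0.625
        obj = accuracy_report(load_reference_table("object")).rounded()
        assert obj["UA"]["BA"] == 0.733

    def test_empty_margin_is_undefined_not_zero(self):
        t1 = load_reference_table("visual_interpretation")
        assert user_accuracy(t1, "RA") is None  # printed as NA
        assert producer_accuracy(t1, "RA") == 0.0

    def test_totals(self):
        assert load_reference_table("visual_interpretation").n == 42
        assert load_reference_table("dnn").n == 5000


class TestAgreementLabels:
    @pytest.mark.parametrize(
        "k,label",
        [
            (0.618, "substantial"),
            (-0.05, "poor"),
            (0.205, "fair"),  # above the 0.20 bin edge
            (0.10, "slight"),
            (0.50, "moderate"),
            (0.95, "almost perfect"),
        ],
    )
    def test_landis_koch_bins(self, k, label):
        assert agreement_label(k) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agreement_label(1.5)


class TestSamplePoints:
    def test_every_pixel_once_when_n_equals_size(self):
        pts = sample_points((4, 5), 20, seed=0)
        assert len({(r, c) for r, c in pts}) == 20

    def test_deterministic_per_seed(self):
        np.testing.assert_array_equal(
            sample_points((50, 60), 100, seed=3), sample_points((50, 60), 100, seed=3)
        )

    def test_points_inside_region(self):
        pts = sample_points((30, 40), 500, seed=1)
        assert (pts[:, 0] < 30).all() and (pts[:, 1] < 40).all()
        assert (pts >= 0).all()

    def test_oversampling_without_replacement_rejected(self):
        with pytest.raises(ValueError, match="replacement"):
            sample_points((3, 3), 10, seed=0)


class TestConfusion:
    def test_identical_maps_give_diagonal(self, rng):
        lab = LabelMap(rng.integers(0, 5, (20, 20)).astype(np.uint8))
        pts = sample_points((20, 20), 400, seed=0)
        cm = confusion(lab, lab, pts)
        assert np.trace(cm.counts) == cm.n == 400

    def test_swapping_transposes(self, rng):
        a = LabelMap(rng.integers(0, 5, (20, 20)).astype(np.uint8))
        b = LabelMap(rng.integers(0, 5, (20, 20)).astype(np.uint8))
        pts = sample_points((20, 20), 200, seed=1)
        classes = ["ZM", "ZM1", "ZM2", "ZM3", "ZJ"]
        cm_ab = confusion(a, b, pts, classes=classes)
        cm_ba = confusion(b, a, pts, classes=classes)
        np.testing.assert_array_equal(cm_ab.counts, cm_ba.counts.T)

    def test_single_point(self):
        a = LabelMap(np.full((2, 2), label_index("GA"), dtype=np.uint8))
        b = LabelMap(np.full((2, 2), label_index("BA"), dtype=np.uint8))
        cm = confusion(a, b, np.array([[0, 0]]))
        assert cm.n == 1
        assert cm.counts[cm.classes.index("GA"), cm.classes.index("BA")] == 1

    def test_unlabeled_truth_points_skipped(self):
        a = LabelMap(np.full((2, 2), label_index("GA"), dtype=np.uint8))
        t = LabelMap(np.full((2, 2), UNLABELED_INDEX, dtype=np.uint8))
        t.labels[0, 0] = label_index("GA")
        cm = confusion(a, t, np.array([[0, 0], [1, 1]]))
        assert cm.n == 1

    def test_dimension_mismatch_rejected(self):
        a = LabelMap(np.zeros((2, 2), dtype=np.uint8))
        b = LabelMap(np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="mismatch"):
            confusion(a, b, np.array([[0, 0]]))


class TestMatrixCsv:
    def test_write_parse_round_trip(self, tmp_path, rng):
        cm = ConfusionMatrix(list("ABC"), rng.integers(0, 50, (3, 3)))
        write_matrix_csv(cm, tmp_path / "m.csv")
        back = parse_matrix_csv(tmp_path / "m.csv")
        assert back.classes == cm.classes
        np.testing.assert_array_equal(back.counts, cm.counts)

    def test_corrupted_total_warns(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            ",A,B,Total\nA,5,1,6\nB,2,2,4\nTotal,7,3,11\n"  # 11 should be 10
        )
        with pytest.warns(UserWarning, match="total"):
            parse_matrix_csv(tmp_path / "bad.csv")

    def test_non_integer_cell_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text(",A,B\nA,5,x\nB,2,2\n")
        with pytest.raises(ValueError, match="non-integer"):
            parse_matrix_csv(tmp_path / "bad.csv")

    def test_ragged_row_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text(",A,B\nA,5\nB,2,2\n")
        with pytest.raises(ValueError, match="ragged"):
            parse_matrix_csv(tmp_path / "bad.csv")


class TestSaltPepper:
    def test_latin_tiling_is_all_speckle(self):
        # 3x3 Latin tiling: every pixel disagrees with all 8 neighbors
        i, j = np.mgrid[0:9, 0:9]
        lab = LabelMap((3 * (i % 3) + j % 3).astype(np.uint8))
        assert salt_pepper_fraction(lab) == 1.0

    def test_uniform_map_no_speckle(self):
        assert salt_pepper_fraction(LabelMap(np.zeros((9, 9), dtype=np.uint8))) == 0.0
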