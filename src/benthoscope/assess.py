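"""Accuracy assessment: random points, confusion matrices, OA / kappa / UA / PA.

The assessment protocol is the standard thematic-map one: draw random points
in the validation region, cross-tabulate mapped class against ground truth,
and report overall accuracy (OA, the fraction of points mapped correctly),
Cohen's kappa (chance-corrected agreement), and per-class user accuracy
(UA = diagonal / row total, the commission view) and producer accuracy
(PA = diagonal / column total, the omission view).  Kappa values are
translated to the Landis–Koch agreement adjectives.

Conventions:

* matrix rows = mapped class, columns = ground-truth class;
* metrics are reported to 3 decimal places, rounded half-up;
* UA/PA with an empty margin are *undefined* (rendered "NA"), never 0;
* points whose ground truth is UNLABELED are skipped and reported.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np

from .raster_io import UNLABELED_INDEX, LabelMap, label_code, label_index

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "sample_points",
    "confusion",
    "overall_accuracy",
    "kappa",
    "user_accuracy",
    "producer_accuracy",
    "agreement_label",
    "accuracy_report",
    "salt_pepper_fraction",
    "parse_matrix_csv",
    "write_matrix_csv",
    "load_reference_table",
    "REFERENCE_TABLES",
]

logger = logging.getLogger(__name__)

#: Shipped fixtures transcribed from the printed confusion matrices:
#: visual interpretation vs field data, and the three mapping methods vs
#: the visual-interpretation ground truth (5,000 random points each).
REFERENCE_TABLES = {
    "visual_interpretation": "table1_visual_interpretation.csv",
    "pixel": "table2a_pixel.csv",
    "object": "table2b_object.csv",
    "dnn": "table2c_dnn.csv",
}


@dataclass
class ConfusionMatrix:
    """Square integer cross-tabulation; rows = mapped, columns = truth."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class AccuracyReport:
    """OA, kappa, per-class UA/PA (None where undefined) and agreement label."""

    oa: float
    kappa: float
    ua: dict[str, float | None]
    pa: dict[str, float | None]
    agreement: str
    n: int
    skipped_unlabeled: int = 0

    def rounded(self, places: int = 3) -> dict:
        """Report dict with metrics rounded half-up, as in printed tables."""

        def r(x):
            if x is None:
                return "NA"
            return float(Decimal(repr(x)).quantize(
                Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))

        return {
            "OA": r(self.oa),
            "K": r(self.kappa),
            "UA": {c: r(v) for c, v in self.ua.items()},
            "PA": {c: r(v) for c, v in self.pa.items()},
            "agreement": self.agreement,
            "n": self.n,
            "skipped_unlabeled": self.skipped_unlabeled,
        }


def sample_points(
    dims: tuple[int, int], n: int, seed: int | np.random.Generator,
    replace: bool = False,
) -> np.ndarray:
    """Draw ``n`` random pixel coordinates uniformly over an H x W region.

    Without replacement by default (each pixel at most once); ``n`` larger
    than the region raises.  Returns an (n, 2) array of (row, col),
    deterministic for a fixed seed.
    """
    h, w = dims
    if n < 1:
        raise ValueError("n must be >= 1")
    size = h * w
    if not replace and n > size:
        raise ValueError(f"cannot draw {n} points without replacement from {size} pixels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.choice(size, size=n, replace=replace)
    return np.stack(np.unravel_index(flat, (h, w)), axis=1)


def confusion(
    mapped: LabelMap, truth: LabelMap, points: np.ndarray,
    classes: list[str] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate mapped vs truth labels at the given points.

    UNLABELED truth points are skipped (logged); counts sum to the number of
    retained points.
    """
    if mapped.shape != truth.shape:
        raise ValueError(f"dimension mismatch: mapped {mapped.shape} vs truth {truth.shape}")
    points = np.asarray(points)
    rows, cols = points[:, 0], points[:, 1]
    m = mapped.labels[rows, cols]
    t = truth.labels[rows, cols]
    keep = t != UNLABELED_INDEX
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipped %d UNLABELED ground-truth points", n_skipped)
    m, t = m[keep], t[keep]
    if classes is None:
        classes = [label_code(i) for i in np.unique(np.concatenate([m, t]))]
    idx = {label_index(c): j for j, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (np.vectorize(idx.get)(m), np.vectorize(idx.get)(t)), 1)
    cm = ConfusionMatrix(list(classes), counts)
    cm.skipped_unlabeled = n_skipped  # type: ignore[attr-defined]
    return cm


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of points classified correctly: trace / n."""
    n = cm.n
    if n == 0:
        raise ValueError("overall accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts)) / n


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from the margins."""
    n = cm.n
    if n == 0:
        raise ValueError("kappa undefined for an empty matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.row_totals() @ cm.col_totals()) / (n * n)
    if p_e == 1.0:
        raise ValueError("kappa undefined when chance agreement equals 1")
    return float((p_o - p_e) / (1.0 - p_e))


def user_accuracy(cm: ConfusionMatrix, cls: str) -> float | None:
    """diagonal / row total; None (undefined) for an empty row."""
    i = cm.classes.index(cls)
    total = cm.row_totals()[i]
    if total == 0:
        return None
    return float(cm.counts[i, i]) / float(total)


def producer_accuracy(cm: ConfusionMatrix, cls: str) -> float | None:
    """diagonal / column total; None (undefined) for an empty column."""
    i = cm.classes.index(cls)
    total = cm.col_totals()[i]
    if total == 0:
        return None
    return float(cm.counts[i, i]) / float(total)


def agreement_label(k: float) -> str:
    """Landis–Koch adjective for a kappa value.

    <0 poor, <=0.20 slight, <=0.40 fair, <=0.60 moderate, <=0.80 substantial;
    above 0.80 "almost perfect" (standard extension of the published scale).
    """
    if not -1.0 <= k <= 1.0:
        raise ValueError(f"kappa {k} outside [-1, 1]")
    if k < 0.0:
        return "poor"
    if k <= 0.20:
        return "slight"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "almost perfect"


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Full accuracy report for a confusion matrix.

    Classes absent from both margins are dropped from per-class reporting
    (logged).
    """
    present = [
        c for j, c in enumerate(cm.classes)
        if cm.row_totals()[j] > 0 or cm.col_totals()[j] > 0
    ]
    dropped = set(cm.classes) - set(present)
    if dropped:
        logger.info("classes absent from both margins dropped: %s", sorted(dropped))
    k = kappa(cm)
    return AccuracyReport(
        oa=overall_accuracy(cm),
        kappa=k,
        ua={c: user_accuracy(cm, c) for c in present},
        pa={c: producer_accuracy(cm, c) for c in present},
        agreement=agreement_label(k),
        n=cm.n,
        skipped_unlabeled=getattr(cm, "skipped_unlabeled", 0),
    )


def salt_pepper_fraction(labelmap: LabelMap) -> float:
    """Fraction of interior pixels that disagree with all 8 neighbors.

    The salt-and-pepper phenomenon — isolated single-pixel speckle — is the
    characteristic failure of per-pixel classification on very high resolution
    imagery; object-based and translation maps suppress it.
    """
    lab = labelmap.labels
    if lab.shape[0] < 3 or lab.shape[1] < 3:
        return 0.0
    center = lab[1:-1, 1:-1]
    isolated = np.ones(center.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = lab[1 + dr:lab.shape[0] - 1 + dr, 1 + dc:lab.shape[1] - 1 + dc]
            isolated &= nb != center
    return float(isolated.mean())


# ---------------------------------------------------------------------------
# confusion-matrix CSV dialect (fixtures for the printed tables)


def parse_matrix_csv(path: str | Path) -> ConfusionMatrix:
    """Parse a confusion-matrix CSV.

    Dialect: first cell empty, ground-truth classes across the header,
    mapped classes down the first column, integer cells.  An optional
    ``Total`` row/column is cross-checked against recomputed margins; a
    mismatch raises a warning (the counts themselves win).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError(f"{path.name}: empty matrix file")
    header = [c.strip() for c in rows[0]]
    if header[0]:
        raise ValueError(f"{path.name}: first header cell must be empty")
    truth_classes = header[1:]
    has_total_col = bool(truth_classes) and truth_classes[-1].lower() == "total"
    if has_total_col:
        truth_classes = truth_classes[:-1]
    width = len(header)
    mapped_classes: list[str] = []
    counts: list[list[int]] = []
    printed_row_totals: list[int] = []
    printed_col_totals: list[int] | None = None
    printed_grand_total: int | None = None
    for r_i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path.name}: ragged row {r_i} ({len(row)} cells, expected {width})")
        name = row[0].strip()
        try:
            cells = [int(c) for c in row[1:]]
        except ValueError as e:
            bad = next(c for c in row[1:] if not c.strip().lstrip("-").isdigit())
            raise ValueError(f"{path.name}: non-integer cell {bad!r} in row {r_i}") from e
        if name.lower() == "total":
            printed_col_totals = cells[: len(truth_classes)]
            if has_total_col:
                printed_grand_total = cells[-1]
            continue
        mapped_classes.append(name)
        counts.append(cells[: len(truth_classes)])
        if has_total_col:
            printed_row_totals.append(cells[-1])
    if mapped_classes != truth_classes:
        raise ValueError(
            f"{path.name}: mapped classes {mapped_classes} != truth classes {truth_classes}"
        )
    cm = ConfusionMatrix(mapped_classes, np.array(counts, dtype=np.int64))
    if has_total_col and printed_row_totals:
        actual = cm.row_totals().tolist()
        if actual != printed_row_totals:
            warnings.warn(
                f"{path.name}: printed row totals {printed_row_totals} != recomputed {actual}"
            )
    if printed_col_totals is not None:
        actual = cm.col_totals().tolist()
        if actual != printed_col_totals:
            warnings.warn(
                f"{path.name}: printed column totals {printed_col_totals} != recomputed {actual}"
            )
    if printed_grand_total is not None and printed_grand_total != cm.n:
        warnings.warn(
            f"{path.name}: printed grand total {printed_grand_total} != recomputed {cm.n}"
        )
    return cm


def write_matrix_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    """Write a confusion matrix in the fixture dialect (with Total margins)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + cm.classes + ["Total"])
        for i, cls in enumerate(cm.classes):
            w.writerow([cls] + cm.counts[i].tolist() + [int(cm.row_totals()[i])])
        w.writerow(["Total"] + cm.col_totals().tolist() + [cm.n])


def load_reference_table(name: str) -> ConfusionMatrix:
    """Load one of the shipped printed-table fixtures by key.

    Keys: ``visual_interpretation`` (transect-survey validation of the
    hand-interpreted map, 42 quadrats) and ``pixel`` / ``object`` / ``dnn``
    (the three mapping methods at 5,000 validation points).
    """
    fname = REFERENCE_TABLES[name]
    ref = resources.files("benthoscope.data.tables") / fname
    with resources.as_file(ref) as p:
        return parse_matrix_csv(p)
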