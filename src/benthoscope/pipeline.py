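"""End-to-end orchestration: simulate -> split -> map (3 methods) -> assess.

One run generates a synthetic scene, splits it into training and validation
regions along the depth axis, produces a map of the validation region with
each requested method — per-pixel SVM, object-based SVM, and cGAN image
translation — and scores all maps against the ground truth at one shared
set of random assessment points, so the comparison is paired.  Outputs are
written as PNG maps, confusion-matrix CSVs in the fixture dialect, a JSON
report, and a JSON-lines stage log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assess import (
    AccuracyReport,
    accuracy_report,
    confusion,
    salt_pepper_fraction,
    sample_points,
    write_matrix_csv,
)
from .augment import flip_augment
from .conventional import (
    SegmentationParams,
    object_svm_fit,
    pixel_svm_fit,
    predict_object_map,
    predict_pixel_map,
    sample_training_polygons,
    segment,
)
from .pix2pix_model import GanConfig, train, translate
from .raster_io import CLASSES, encode_labels, write_image, write_labels
from .scene_sim import SceneConfig, default_scene_config, generate_scene
from .subclass import PosterizeConfig, posterize_training_tiles
from .tiling import RegionSplit, slice_tiles, split_scene

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "report_tables"]

logger = logging.getLogger(__name__)

METHODS = ("pixel", "object", "dnn")


@dataclass
class RunConfig:
    """Everything one comparison run needs, with seeds."""

    scene: SceneConfig = None  # type: ignore[assignment]
    tile_size: int = 64
    train_fraction: float = 0.54
    methods: tuple[str, ...] = METHODS
    n_points: int = 5000
    assess_seed: int = 7
    polygon_seed: int = 11
    gan: GanConfig = field(default_factory=GanConfig)
    posterize: PosterizeConfig = field(default_factory=PosterizeConfig)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.scene is None:
            self.scene = default_scene_config()
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass
class ComparisonReport:
    """Per-method accuracy, speckle metric, and OA/kappa rankings."""

    reports: dict[str, AccuracyReport]
    salt_pepper: dict[str, float]
    matrix_paths: dict[str, str]
    ranking_by_oa: list[str]
    ranking_by_kappa: list[str]

    def to_dict(self) -> dict:
        return {
            "methods": {m: r.rounded() for m, r in self.reports.items()},
            "salt_pepper": {m: round(v, 5) for m, v in self.salt_pepper.items()},
            "matrix_paths": self.matrix_paths,
            "ranking_by_oa": self.ranking_by_oa,
            "ranking_by_kappa": self.ranking_by_kappa,
        }


class _StageLog:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def stage(self, name: str, **params):
        return _StageTimer(self, name, params)

    def write(self, record: dict):
        logger.info("stage %(stage)s done in %(seconds).2fs", record)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record) + "\n")


class _StageTimer:
    def __init__(self, log, name, params):
        self.log, self.name, self.params = log, name, params

    def __enter__(self):
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        rec = {"stage": self.name, "params": self.params,
               "seconds": time.monotonic() - self.t0}
        if exc_type is not None:
            rec["failed"] = repr(exc)
        self.log.write(rec)
        return False


def _map_pixel(cfg: RunConfig, train_scene, valid_scene):
    polygons = sample_training_polygons(train_scene.truth, cfg.polygon_seed)
    clf = pixel_svm_fit(train_scene.image, polygons, seed=cfg.polygon_seed)
    return predict_pixel_map(clf, valid_scene.image)


def _map_object(cfg: RunConfig, train_scene, valid_scene):
    # a distinct polygon stream, as the two baselines were fed different sets
    polygons = sample_training_polygons(train_scene.truth, cfg.polygon_seed + 1)
    seg_train = segment(train_scene.image, cfg.seg_params)
    clf = object_svm_fit(train_scene.image, seg_train, polygons)
    seg_valid = segment(valid_scene.image, cfg.seg_params)
    return predict_object_map(clf, valid_scene.image, seg_valid)


def _map_dnn(cfg: RunConfig, train_scene, valid_scene):
    tiles = slice_tiles(train_scene, cfg.tile_size, region="train")
    tiles = posterize_training_tiles(tiles, cfg.posterize)
    tiles = flip_augment(tiles)
    model = train(tiles, cfg.gan)
    return translate(model, valid_scene.image)


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Run the full comparison; see the module docstring.

    Deterministic for fixed seeds in the pixel/object stages; the cGAN seed
    is recorded in the config so stochastic runs are re-runnable.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out_dir / "run_log.jsonl" if out_dir else None)

    with log.stage("simulate", seed=config.scene.seed,
                   size=(config.scene.height, config.scene.width)):
        scene = generate_scene(config.scene)
    with log.stage("split", train_fraction=config.train_fraction,
                   tile_size=config.tile_size):
        split = RegionSplit(train_fraction=config.train_fraction)
        train_scene, valid_scene, resolved = split_scene(scene, split, config.tile_size)
    if out_dir:
        write_image(scene.image, out_dir / "scene.png")
        write_labels(scene.truth, out_dir / "truth.png")

    mappers = {"pixel": _map_pixel, "object": _map_object, "dnn": _map_dnn}
    maps = {}
    for method in config.methods:
        with log.stage(method):
            try:
                maps[method] = mappers[method](config, train_scene, valid_scene)
            except Exception:
                if out_dir:
                    (out_dir / "failed").mkdir(exist_ok=True)
                    (out_dir / "failed" / f"{method}.marker").write_text(
                        "stage failed; see log"
                    )
                raise

    # one shared point set so the method comparison is paired
    with log.stage("assess", n=config.n_points, seed=config.assess_seed):
        vh, vw = valid_scene.truth.shape
        points = sample_points((vh, vw), config.n_points, config.assess_seed)
        reports, sp, matrix_paths = {}, {}, {}
        for method, mapped in maps.items():
            mh, mw = mapped.shape
            pts = points[(points[:, 0] < mh) & (points[:, 1] < mw)]
            truth_crop = valid_scene.truth
            if (mh, mw) != (vh, vw):  # translation map may crop residual margins
                from .raster_io import LabelMap

                truth_crop = LabelMap(valid_scene.truth.labels[:mh, :mw])
            cm = confusion(mapped, truth_crop, pts, classes=list(CLASSES))
            reports[method] = accuracy_report(cm)
            sp[method] = salt_pepper_fraction(mapped)
            if out_dir:
                p = out_dir / f"confusion_{method}.csv"
                write_matrix_csv(cm, p)
                matrix_paths[method] = str(p)
                write_labels(mapped, out_dir / f"map_{method}.png")
                write_image(
                    type(valid_scene.image)(encode_labels(mapped)),
                    out_dir / f"map_{method}_rgb.png",
                )

    order_oa = sorted(reports, key=lambda m: reports[m].oa, reverse=True)
    order_k = sorted(reports, key=lambda m: reports[m].kappa, reverse=True)
    report = ComparisonReport(reports, sp, matrix_paths, order_oa, order_k)
    if out_dir:
        report_tables(report, out_dir)
    return report


def report_tables(report: ComparisonReport, out_dir: str | Path) -> Path:
    """Emit the comparison as JSON (matrix CSVs are written during the run)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "comparison_report.json"
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return path
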