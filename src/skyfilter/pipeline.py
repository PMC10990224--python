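"""End-to-end 3-stage workflow: filter -> detect -> (classify stub).

Orchestrates the whole in-flight processing chain over a dataset directory
produced by :func:`skyfilter.synthetic.generate_dataset` (or any dataset in
the same layout): stage 1 scores every parent frame for bird occurrence and
keeps those above the threshold, stage 2 runs the blob+HOG+SVM detector on
the kept frames (tiled with the inference grid, merged with NMS), and
stage 3 — the species-classification slot, deliberately an explicit no-op —
labels every detection ``bird-unclassified``.  All imagery and per-stage
outputs are retained regardless of filter decisions so filter error rates
can be estimated afterwards; dropped parents that contained ground truth
(the population-bias mode of a first-stage filter) are listed explicitly in
the run record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .blob_detector import BlobSvmDetector
from .core import AnnotationSet, BoundingBox, DetectionSet, ParentImage
from .detect_eval import EvalReport, evaluate, image_level_metrics, stratify_by_gsd
from .imagery_io import (RunConfig, read_coco, read_image, read_manifest,
                         write_detections)
from .occupancy_filter import filter_images, make_patch_dataset, train_filter
from .tiler import extract_patch, merge_detections, plan_tiles

__all__ = ["RunRecord", "PipelineStageError", "run_workflow",
           "RegionData", "crossval_regions"]

logger = logging.getLogger(__name__)

STUB_LABEL = "bird-unclassified"


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the last good artifact."""

    def __init__(self, stage: str, last_artifact: Optional[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {last_artifact!r}: {cause}")
        self.stage = stage
        self.last_artifact = last_artifact


@dataclass
class RunRecord:
    config: dict
    seeds: dict
    n_parents: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped_with_gt: List[object] = field(default_factory=list)
    n_detections_raw: int = 0
    n_detections_merged: int = 0
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    output_paths: Dict[str, str] = field(default_factory=dict)
    report: Optional[EvalReport] = None
    image_probs: Optional[pd.DataFrame] = None
    detections: Optional[DetectionSet] = None


def _load_dataset(cfg: RunConfig):
    root = Path(cfg.data.dataset_dir)
    manifest = read_manifest(root / "manifest.csv")
    ann_key = cfg.data.annotations
    if ann_key in ("tight", "loose"):
        ann_path = root / f"annotations_{ann_key}.json"
    else:
        ann_path = Path(ann_key)
    annotations = read_coco(ann_path)
    images = {
        row.image_id: read_image(root / "images" / row.file_name)
        for row in manifest.itertuples()
    }
    return manifest, annotations, images


def _detect_parent(detector: BlobSvmDetector, image: np.ndarray,
                   window: int, stride: int, nms_iou: float):
    """Tile one parent with the inference grid, detect per patch, merge."""
    h, w = image.shape[:2]
    grid = plan_tiles(w, h, (window, window), (stride, stride))
    per_tile = []
    n_raw = 0
    for tile in grid:
        patch = extract_patch(image, tile)
        dets = detector.predict_image(patch)
        n_raw += len(dets)
        per_tile.append((tile, dets))
    merged = merge_detections(per_tile, nms_iou=nms_iou)
    return merged, n_raw


def run_workflow(config: RunConfig) -> RunRecord:
    """Run the full 3-stage workflow under one resolved configuration.

    Requires ``config.data.dataset_dir`` (dataset layout of
    :func:`generate_dataset`) and ``config.data.out_dir`` for artifacts.
    Models are trained on the manifest's ``train`` split; filtering,
    detection and evaluation run on the remaining splits.
    """
    if config.data.dataset_dir is None or config.data.out_dir is None:
        raise ValueError("config.data.dataset_dir and out_dir are required")
    out = Path(config.data.out_dir)
    (out / "filter").mkdir(parents=True, exist_ok=True)
    (out / "detect").mkdir(exist_ok=True)
    (out / "eval").mkdir(exist_ok=True)
    log_lines: List[str] = []
    record = RunRecord(config=config.model_dump(), seeds={"seed": config.seed})
    last_artifact: Optional[str] = None

    def _log(msg: str):
        logger.info(msg)
        log_lines.append(msg)

    lock_path = out / "config.lock.yaml"
    lock_path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    record.output_paths["config"] = str(lock_path)
    last_artifact = str(lock_path)

    # ---- load data ----------------------------------------------------
    try:
        manifest, annotations, images = _load_dataset(config)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("load", last_artifact, e) from e
    train_rows = manifest[manifest.split == "train"]
    eval_rows = manifest[manifest.split != "train"]
    if len(eval_rows) == 0:
        eval_rows = manifest
    _log(f"dataset: {len(manifest)} parents ({len(train_rows)} train)")

    # ---- train models -------------------------------------------------
    t0 = time.perf_counter()
    try:
        train_images = [images[r.image_id] for r in train_rows.itertuples()]
        train_boxes = [annotations.boxes.get(r.image_id, [])
                       for r in train_rows.itertuples()]
        patches, labels = make_patch_dataset(
            train_images, train_boxes,
            window=config.tiling.train.window,
            stride=config.tiling.train.stride,
            n_augments=2, seed=config.seed)
        filter_kw = ({"random_state": config.seed}
                     if config.filter.backend == "small_cnn" else {})
        filter_model = train_filter(patches, labels,
                                    backend=config.filter.backend,
                                    **filter_kw)
        occupied = [(r.image_id, len(annotations.boxes.get(r.image_id, [])) > 0)
                    for r in train_rows.itertuples()]
        det_train = [(images[i], annotations.boxes.get(i, []))
                     for i, occ in occupied if occ]
        if not det_train:
            # nothing to learn from: a bird-free training split can still
            # exercise the filter, but detection must stand down
            detector = None
            _log("no occupied training images; detection stage will emit "
                 "no boxes")
        else:
            detector = BlobSvmDetector(
                intensity_threshold=config.blob.intensity_threshold,
                dilation_factor=config.blob.dilation_factor,
                polarity=config.blob.polarity,
                contrast_enhance=config.blob.contrast_enhance,
                min_blob_px=config.blob.min_blob_px,
                hog_window=config.hog.window, hog_cell=config.hog.cell,
                hog_block=config.hog.block,
                hog_orientations=config.hog.orientations,
                random_state=config.seed,
            )
            detector.fit([im for im, _ in det_train], [g for _, g in det_train])
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("train", last_artifact, e) from e
    record.stage_seconds["train"] = time.perf_counter() - t0

    # ---- stage 1: occupancy filter ------------------------------------
    t0 = time.perf_counter()
    try:
        parents = [
            ParentImage(r.image_id, images[r.image_id], r.gsd_cm,
                        annotations.boxes.get(r.image_id, []))
            for r in eval_rows.itertuples()
        ]
        kept, dropped, probs = filter_images(
            filter_model, parents,
            window=config.tiling.eval.window,
            stride=config.tiling.eval.stride,
            rescale=config.tiling.eval.rescale,
            threshold=config.filter.threshold)
        probs_path = out / "filter" / "probs.csv"
        probs.to_csv(probs_path, index=False)
        record.output_paths["filter_probs"] = str(probs_path)
        last_artifact = str(probs_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("filter", last_artifact, e) from e
    record.stage_seconds["filter"] = time.perf_counter() - t0
    record.n_parents = len(parents)
    record.n_kept, record.n_dropped = len(kept), len(dropped)
    record.image_probs = probs
    record.dropped_with_gt = [
        i for i in dropped if len(annotations.boxes.get(i, [])) > 0]
    for i in record.dropped_with_gt:
        _log(f"WARNING: dropped parent {i} contains ground-truth birds "
             "(false-negative filter prediction)")

    # ---- stage 2: detection + NMS merge -------------------------------
    t0 = time.perf_counter()
    try:
        det_boxes: Dict[object, List[BoundingBox]] = {}
        n_raw = 0
        for parent in parents:
            if detector is not None and parent.image_id in kept:
                merged, raw = _detect_parent(
                    detector, parent.image,
                    config.tiling.eval.window, config.tiling.eval.stride,
                    config.nms.iou)
                n_raw += raw
            else:
                merged = []
            det_boxes[parent.image_id] = merged
        # stage 3 stub: the classification slot labels every instance
        det_boxes = {
            i: [dataclasses.replace(b, label=STUB_LABEL) for b in bs]
            for i, bs in det_boxes.items()
        }
        detections = DetectionSet(det_boxes)
        dets_path = out / "detect" / "dets.json"
        write_detections(detections, dets_path)
        record.output_paths["detections"] = str(dets_path)
        last_artifact = str(dets_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("detect", last_artifact, e) from e
    record.stage_seconds["detect"] = time.perf_counter() - t0
    record.n_detections_raw = n_raw
    record.n_detections_merged = detections.n_boxes()
    record.detections = detections

    # ---- evaluation ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        gts = AnnotationSet(
            {p.image_id: annotations.boxes.get(p.image_id, []) for p in parents},
            categories=annotations.categories)
        report = evaluate(detections, gts, iou_grid=config.eval.iou_grid())
        pred = {r.image_id: int(r.decision) for r in probs.itertuples()}
        truth = {p.image_id: int(len(p.gt_boxes or [])) > 0 for p in parents}
        report.image_level = image_level_metrics(pred, truth)
        gsd = {p.image_id: p.gsd_cm for p in parents}
        if len({round(g, 6) for g in gsd.values()}) > 1:
            report.per_gsd_bin = stratify_by_gsd(
                detections, gts, gsd, bin_edges=config.eval.gsd_bins,
                iou_grid=config.eval.iou_grid())
        report_path = out / "eval" / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        record.output_paths["report"] = str(report_path)
        last_artifact = str(report_path)
        record.report = report
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("evaluate", last_artifact, e) from e
    record.stage_seconds["evaluate"] = time.perf_counter() - t0

    _log(f"kept {record.n_kept}/{record.n_parents} parents; "
         f"{record.n_detections_merged} detections after NMS")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    record.output_paths["log"] = str(out / "log.txt")
    return record


# ---------------------------------------------------------------------------
# cross-region validation


@dataclass
class RegionData:
    """Labeled data for one survey region/regime."""

    name: str
    train_images: Sequence[np.ndarray]
    train_boxes: Sequence[Sequence[BoundingBox]]
    val_images: Dict[object, np.ndarray]
    val_annotations: AnnotationSet


def crossval_regions(config: RunConfig, region_a: RegionData,
                     region_b: RegionData) -> pd.DataFrame:
    """Train one detector per region and evaluate both on region A's
    validation split, yielding a 2-row mAP/mAP50/mAP75/AR table that
    isolates the effect of the training region."""
    rows = []
    for region in (region_a, region_b):
        if not any(len(b) > 0 for b in region.train_boxes):
            raise ValueError(f"region {region.name!r} has no positive training data")
        detector = BlobSvmDetector(
            intensity_threshold=config.blob.intensity_threshold,
            dilation_factor=config.blob.dilation_factor,
            polarity=config.blob.polarity,
            contrast_enhance=config.blob.contrast_enhance,
            min_blob_px=config.blob.min_blob_px,
            random_state=config.seed,
        )
        detector.fit(list(region.train_images), list(region.train_boxes))
        det_boxes = {
            img_id: detector.predict_image(img)
            for img_id, img in region_a.val_images.items()
        }
        report = evaluate(DetectionSet(det_boxes), region_a.val_annotations,
                          iou_grid=config.eval.iou_grid())
        rows.append({
            "train_region": region.name,
            "mAP": report.mean_ap, "mAP50": report.map50,
            "mAP75": report.map75, "AR": report.average_recall,
        })
    return pd.DataFrame(rows, columns=["train_region", "mAP", "mAP50",
                                       "mAP75", "AR"])
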