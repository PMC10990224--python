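"""Readers and writers for images, COCO-style annotations, manifests and
the YAML run configuration.

The COCO dialect used throughout: object-detection JSON with
``images``/``annotations``/``categories``; ``bbox`` as ``[x, y, w, h]`` in
pixels, 0-based, top-left origin.  Internally boxes are half-open
``[x0, x1) x [y0, y1)`` (see :mod:`skyfilter.core`); these converters are
the only place the two conventions meet.  Ground-sample distance is carried
in the manifest CSV, not in the COCO files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core import AnnotationSet, BoundingBox, DetectionSet

__all__ = [
    "read_coco",
    "write_coco",
    "read_detections",
    "write_detections",
    "read_image",
    "read_manifest",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# images


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF frame as a float array in [0, 1], collapsing RGB to
    luminance."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype == np.uint16:
        arr = arr / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr


# ---------------------------------------------------------------------------
# COCO annotations


def read_coco(path) -> AnnotationSet:
    """Read ground-truth boxes from a COCO-style JSON file.

    Boxes with non-positive width or height are rejected with the index of
    the offending annotation record.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed COCO JSON in {path}: {e}") from e
    image_ids = [img["id"] for img in data.get("images", [])]
    boxes: Dict[object, List[BoundingBox]] = {i: [] for i in image_ids}
    categories = {c["id"]: c["name"] for c in data.get("categories", [])}
    cat_names = dict(categories)
    for idx, ann in enumerate(data.get("annotations", [])):
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(
                f"annotation record {idx} (id={ann.get('id')}) has "
                f"non-positive bbox size {w}x{h}"
            )
        label = cat_names.get(ann.get("category_id"))
        boxes.setdefault(ann["image_id"], []).append(
            BoundingBox.from_xywh([x, y, w, h], label=label)
        )
    return AnnotationSet(boxes=boxes, categories=categories or {1: "bird"})


def write_coco(annotations: AnnotationSet, path,
               sizes: Optional[Dict[object, Tuple[int, int]]] = None,
               file_names: Optional[Dict[object, str]] = None) -> Path:
    """Write an :class:`AnnotationSet` to COCO-style JSON; round-trips
    losslessly through :func:`read_coco` for geometry, ids and categories."""
    path = Path(path)
    name_of = {v: k for k, v in annotations.categories.items()}
    images, anns = [], []
    ann_id = 1
    for img_id in annotations.image_ids():
        entry = {"id": img_id}
        if file_names and img_id in file_names:
            entry["file_name"] = file_names[img_id]
        if sizes and img_id in sizes:
            entry["width"], entry["height"] = sizes[img_id]
        images.append(entry)
        for b in annotations.boxes[img_id]:
            anns.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": name_of.get(b.label, 1),
                "bbox": list(b.to_xywh()),
                "area": b.area,
                "iscrowd": 0,
            })
            ann_id += 1
    payload = {
        "images": images,
        "annotations": anns,
        "categories": [{"id": k, "name": v}
                       for k, v in sorted(annotations.categories.items())],
    }
    path.write_text(json.dumps(payload, sort_keys=True) + "\n")
    return path


def read_detections(path) -> DetectionSet:
    """Read a COCO-results-style JSON list of scored detections."""
    data = json.loads(Path(path).read_text())
    boxes: Dict[object, List[BoundingBox]] = {}
    for idx, rec in enumerate(data):
        x, y, w, h = rec["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(f"detection record {idx} has non-positive bbox size")
        boxes.setdefault(rec["image_id"], []).append(
            BoundingBox.from_xywh([x, y, w, h], score=float(rec["score"]))
        )
    return DetectionSet(boxes=boxes)


def write_detections(dets: DetectionSet, path) -> Path:
    path = Path(path)
    recs = [
        {"image_id": img_id, "category_id": 1,
         "bbox": list(b.to_xywh()), "score": b.score}
        for img_id in dets.image_ids()
        for b in dets.boxes[img_id]
    ]
    path.write_text(json.dumps(recs, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read the dataset manifest CSV (image_id, file_name, gsd_cm, split,
    n_birds)."""
    df = pd.read_csv(path)
    required = {"image_id", "file_name", "gsd_cm", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# run configuration


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TilingWindow(_Forbid):
    window: int
    stride: int
    rescale: Optional[int] = None

    @model_validator(mode="after")
    def _check(self):
        if self.window <= 0 or self.stride <= 0:
            raise ValueError("window and stride must be positive")
        if self.stride > self.window:
            raise ValueError(f"stride {self.stride} exceeds window {self.window}")
        if self.rescale is not None and self.rescale <= 0:
            raise ValueError("rescale must be positive")
        return self


class TilingConfig(_Forbid):
    train: TilingWindow = TilingWindow(window=720, stride=540)
    eval: TilingWindow = TilingWindow(window=1440, stride=1080, rescale=960)


class FilterConfig(_Forbid):
    backend: str = "small_cnn"
    threshold: float = 0.5

    @field_validator("threshold")
    @classmethod
    def _thr(cls, v):
        if not (0 < v < 1):
            raise ValueError(f"filter threshold must be in (0, 1), got {v}")
        return v

    @field_validator("backend")
    @classmethod
    def _backend(cls, v):
        if v not in ("small_cnn", "proposal_heuristic"):
            raise ValueError(f"unknown filter backend {v!r}")
        return v


class BlobConfig(_Forbid):
    intensity_threshold: float = 0.9
    dilation_factor: int = 12
    polarity: str = "dark_fg"
    contrast_enhance: str = "none"
    min_blob_px: int = 4

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.intensity_threshold < 1):
            raise ValueError("intensity_threshold must be in (0, 1)")
        if self.dilation_factor < 0:
            raise ValueError("dilation_factor must be non-negative")
        if self.polarity not in ("dark_fg", "bright_fg"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.contrast_enhance not in ("none", "stretch", "clahe"):
            raise ValueError(f"unknown contrast_enhance {self.contrast_enhance!r}")
        return self


class HogConfig(_Forbid):
    window: Tuple[int, int] = (64, 64)
    cell: Tuple[int, int] = (8, 8)
    block: Tuple[int, int] = (2, 2)
    block_stride: Tuple[int, int] = (8, 8)
    orientations: int = 9


class NmsConfig(_Forbid):
    iou: float = 0.5

    @field_validator("iou")
    @classmethod
    def _iou(cls, v):
        if not (0 < v < 1):
            raise ValueError(f"nms iou must be in (0, 1), got {v}")
        return v


class EvalConfig(_Forbid):
    iou_start: float = 0.50
    iou_stop: float = 0.95
    iou_step: float = 0.05
    gsd_bins: Tuple[float, float] = (0.6, 1.2)

    def iou_grid(self):
        n = int(round((self.iou_stop - self.iou_start) / self.iou_step)) + 1
        return [round(self.iou_start + i * self.iou_step, 2) for i in range(n)]


class DataConfig(_Forbid):
    dataset_dir: Optional[str] = None
    out_dir: Optional[str] = None
    annotations: str = "tight"   # tight | loose | explicit path


class RunConfig(_Forbid):
    """Resolved run configuration; defaults are the workflow's standard
    constants (training tiles 720/540, inference tiles 1440/1080 rescaled
    to 960, blob threshold 0.9 and dilation 12, IoU grid 0.50:0.05:0.95,
    GSD bin edges 0.6 and 1.2 cm)."""

    tiling: TilingConfig = Field(default_factory=TilingConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    blob: BlobConfig = Field(default_factory=BlobConfig)
    hog: HogConfig = Field(default_factory=HogConfig)
    nms: NmsConfig = Field(default_factory=NmsConfig)
    eval: EvalConfig = Field(default_factory=EvalConfig)
    data: DataConfig = Field(default_factory=DataConfig)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys.

    Unknown keys raise (catching typos); invalid values raise range errors.
    The fully resolved configuration is echoed to the module logger.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    cfg = RunConfig(**raw)
    logger.info("resolved run config: %s", cfg.model_dump())
    return cfg
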