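"""Core geometric containers shared across the workflow.

Boxes are stored half-open, ``[x0, x1) x [y0, y1)`` in pixel units with a
top-left origin, so that ``area = (x1-x0)*(y1-y0)`` and IoU arithmetic are
unambiguous.  The COCO ``[x, y, w, h]`` convention is met only in the
converters (:func:`BoundingBox.to_xywh` / :func:`BoundingBox.from_xywh`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "BoundingBox",
    "AnnotationSet",
    "DetectionSet",
    "ParentImage",
    "iou",
    "boxes_to_array",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``[x0, x1) x [y0, y1)`` in a stated coordinate frame."""

    x0: float
    y0: float
    x1: float
    y1: float
    score: Optional[float] = None
    label: Optional[str] = None
    frame: str = "parent"

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box: [{self.x0},{self.y0},{self.x1},{self.y1}]"
            )
        if self.score is not None and not np.isfinite(self.score):
            raise ValueError(f"non-finite score {self.score!r}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def to_xywh(self) -> List[float]:
        return [self.x0, self.y0, self.width, self.height]

    @classmethod
    def from_xywh(cls, xywh, **kw) -> "BoundingBox":
        x, y, w, h = xywh
        return cls(x, y, x + w, y + h, **kw)

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return replace(self, x0=self.x0 + dx, y0=self.y0 + dy,
                       x1=self.x1 + dx, y1=self.y1 + dy)

    def scaled(self, sx: float, sy: float) -> "BoundingBox":
        return replace(self, x0=self.x0 * sx, y0=self.y0 * sy,
                       x1=self.x1 * sx, y1=self.y1 * sy)

    def clipped(self, width: float, height: float) -> "BoundingBox":
        """Clip to image bounds ``[0, width) x [0, height)``."""
        return replace(
            self,
            x0=float(np.clip(self.x0, 0, width)),
            y0=float(np.clip(self.y0, 0, height)),
            x1=float(np.clip(self.x1, 0, width)),
            y1=float(np.clip(self.y1, 0, height)),
        )

    def with_score(self, score: float) -> "BoundingBox":
        return replace(self, score=score)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes: area(a & b) / area(a | b)."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def boxes_to_array(boxes) -> np.ndarray:
    """Stack boxes into an ``(n, 4)`` float array of ``x0, y0, x1, y1``."""
    if len(boxes) == 0:
        return np.empty((0, 4), dtype=float)
    return np.asarray([[b.x0, b.y0, b.x1, b.y1] for b in boxes], dtype=float)


@dataclass
class AnnotationSet:
    """Ground-truth boxes keyed by image id, plus the category map."""

    boxes: Dict[object, List[BoundingBox]] = field(default_factory=dict)
    categories: Dict[int, str] = field(default_factory=lambda: {1: "bird"})

    def image_ids(self):
        return list(self.boxes)

    def n_boxes(self) -> int:
        return sum(len(v) for v in self.boxes.values())

    def __getitem__(self, image_id):
        return self.boxes[image_id]


@dataclass
class DetectionSet:
    """Scored predicted boxes keyed by image id."""

    boxes: Dict[object, List[BoundingBox]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id, bs in self.boxes.items():
            for b in bs:
                if b.score is None:
                    raise ValueError(f"unscored detection for image {image_id!r}")

    def image_ids(self):
        return list(self.boxes)

    def n_boxes(self) -> int:
        return sum(len(v) for v in self.boxes.values())

    def __getitem__(self, image_id):
        return self.boxes[image_id]


@dataclass
class ParentImage:
    """A full survey frame with its ground-sample distance (cm/pixel)."""

    image_id: object
    image: np.ndarray
    gsd_cm: float
    gt_boxes: Optional[List[BoundingBox]] = None

    @property
    def shape(self):
        return self.image.shape
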