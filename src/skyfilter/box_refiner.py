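"""Annotation-box refinement: tighten loose manual boxes around targets.

Manual survey annotations are often drawn generously; boxes that include
too many background pixels depress detection training and high-IoU metrics.
This module reproduces the bootstrap refinement idea: compute an activation
map over a padded crop of the loose box, initialize a mask at Otsu's
threshold, evolve a two-phase morphological level set (Chan-Vese-type
energy on the activation map), keep the largest 8-connected foreground
component, and emit its tight bounding box.  If anything degenerates —
flat crop, empty initialization, sub-4-pixel foreground — the original box
is returned unchanged with ``converged=False``.

Two activation backends exist: ``contrast`` (normalized absolute deviation
from the robust background level, needing no trained model) and ``cam``
(class-activation map from any patch classifier exposing spatial feature
maps and class weights, e.g. the occupancy filter's convolutional backend).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.transform import resize as _resize
from sklearn.base import BaseEstimator

from .core import AnnotationSet, BoundingBox, iou as _box_iou

__all__ = [
    "RefinementResult",
    "activation_map",
    "level_set_segment",
    "refine_box",
    "refine_dataset",
    "BoxRefiner",
]

# minimum raw intensity range inside a crop for refinement to engage; below
# this the crop is treated as target-free water and the box is left alone
MIN_TARGET_CONTRAST = 0.1


@dataclass
class RefinementResult:
    original: BoundingBox
    refined: BoundingBox
    converged: bool
    fg_area_px: int


def activation_map(patch: np.ndarray, backend: str = "contrast",
                   classifier=None) -> np.ndarray:
    """Heat map in [0, 1] with the same spatial dims as ``patch``.

    ``contrast``: absolute deviation from the median of the border pixels
    (the robust background level), normalized by its maximum.  ``cam``:
    weighted sum of the classifier's spatial feature maps by its class
    weights, bilinearly upsampled and min-max normalized.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    if backend == "contrast":
        bw = max(1, min(2, patch.shape[0] - 1, patch.shape[1] - 1))
        border = np.concatenate([
            patch[:bw].ravel(), patch[-bw:].ravel(),
            patch[:, :bw].ravel(), patch[:, -bw:].ravel(),
        ])
        heat = np.abs(patch - np.median(border))
        peak = heat.max()
        return heat / peak if peak > 0 else heat
    if backend == "cam":
        if classifier is None:
            raise ValueError("cam backend requires a classifier exposing "
                             "feature_maps() and class_weights_")
        maps = np.asarray(classifier.feature_maps(patch), dtype=float)
        weights = np.asarray(classifier.class_weights_, dtype=float)
        cam = np.tensordot(maps, weights, axes=([2], [0]))
        cam = _resize(cam, patch.shape[:2], order=1, anti_aliasing=False,
                      preserve_range=True)
        lo, hi = cam.min(), cam.max()
        return (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
    raise ValueError(f"unknown activation backend {backend!r}")


# four 3x3 line structuring elements used by the morphological curvature
# smoothing (sup-inf / inf-sup operator pair)
_LINES = [
    np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], bool),
    np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], bool),
    np.eye(3, dtype=bool),
    np.fliplr(np.eye(3, dtype=bool)),
]


def _sup_inf(u: np.ndarray) -> np.ndarray:
    return np.stack([binary_erosion(u, p) for p in _LINES]).max(axis=0)


def _inf_sup(u: np.ndarray) -> np.ndarray:
    return np.stack([binary_dilation(u, p) for p in _LINES]).min(axis=0)


def level_set_segment(heat: np.ndarray, init_mask: np.ndarray,
                      iters: int = 100, smoothing: int = 1) -> np.ndarray:
    """Two-phase morphological level-set evolution on a heat map.

    Each iteration applies a curvature-smoothing step (alternating
    sup-inf/inf-sup morphological operators) and then moves the front
    in/out wherever flipping a boundary pixel lowers the two-phase variance
    energy ``sum_in (h - c_in)^2 + sum_out (h - c_out)^2``.  Evolution
    stops at ``iters`` or once the mask is unchanged for 3 consecutive
    iterations.
    """
    heat = np.asarray(heat, dtype=float)
    u = np.asarray(init_mask, dtype=bool).copy()
    if u.shape != heat.shape:
        raise ValueError("init_mask shape must match heat")
    if not u.any():
        raise ValueError("all-zero init_mask: nothing to evolve")
    unchanged = 0
    for it in range(iters):
        prev = u
        for s in range(smoothing):
            u = _sup_inf(_inf_sup(u)) if (it + s) % 2 else _inf_sup(_sup_inf(u))
        c_in = heat[u].mean() if u.any() else 0.0
        c_out = heat[~u].mean() if (~u).any() else c_in
        boundary = binary_dilation(u) ^ binary_erosion(u)
        force = (heat - c_in) ** 2 - (heat - c_out) ** 2
        u = u.copy()
        u[boundary & (force < 0)] = True
        u[boundary & (force > 0)] = False
        if np.array_equal(u, prev):
            unchanged += 1
            if unchanged >= 3:
                break
        else:
            unchanged = 0
    return u


def refine_box(
    image: np.ndarray,
    loose_box: BoundingBox,
    margin_frac: float = 0.2,
    iters: int = 100,
    backend: str = "contrast",
    classifier=None,
) -> RefinementResult:
    """Tighten one loose box around the target it contains.

    The loose box is expanded by ``margin_frac`` of its size per side
    (clipped to the image), an activation map is computed over the crop,
    the mask initialized at Otsu's threshold is evolved by
    :func:`level_set_segment`, and the tight box of the largest 8-connected
    foreground component is mapped back to parent coordinates.  Fallback to
    the input box (``converged=False``) on any degenerate condition.
    """
    if loose_box.area <= 0:  # unreachable for a valid BoundingBox; guard anyway
        raise ValueError("degenerate loose_box")
    h, w = image.shape[:2]
    mx, my = margin_frac * loose_box.width, margin_frac * loose_box.height
    x0 = int(np.clip(np.floor(loose_box.x0 - mx), 0, w - 1))
    y0 = int(np.clip(np.floor(loose_box.y0 - my), 0, h - 1))
    x1 = int(np.clip(np.ceil(loose_box.x1 + mx), x0 + 1, w))
    y1 = int(np.clip(np.ceil(loose_box.y1 + my), y0 + 1, h))
    crop = np.asarray(image, dtype=float)[y0:y1, x0:x1]

    fallback = RefinementResult(loose_box, loose_box, False, 0)
    if crop.size < 16 or np.ptp(crop) < MIN_TARGET_CONTRAST:
        return fallback
    heat = activation_map(crop, backend=backend, classifier=classifier)
    if np.ptp(heat) < 1e-9:
        return fallback
    try:
        init = heat >= threshold_otsu(heat)
    except ValueError:
        return fallback
    if not init.any():
        return fallback
    mask = level_set_segment(heat, init, iters=iters)
    if not mask.any():
        return fallback
    labels, n = _sk_label(mask, connectivity=2, return_num=True)
    if n == 0:
        return fallback
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    area = int(areas[best - 1])
    if area < 4:
        return fallback
    ys, xs = np.nonzero(labels == best)
    refined = BoundingBox(
        float(x0 + xs.min()), float(y0 + ys.min()),
        float(x0 + xs.max() + 1), float(y0 + ys.max() + 1),
        score=loose_box.score, label=loose_box.label, frame=loose_box.frame,
    )
    return RefinementResult(loose_box, refined, True, area)


def refine_dataset(
    annotations: AnnotationSet,
    images: Dict[object, np.ndarray],
    margin_frac: float = 0.2,
    iters: int = 100,
    backend: str = "contrast",
    classifier=None,
) -> Tuple[AnnotationSet, pd.DataFrame]:
    """Refine every annotation; ids and categories are preserved.

    Returns the refined set and a report with one row per box:
    ``image_id, box_index, iou_original_refined, converged``.
    """
    missing = [i for i in annotations.image_ids() if i not in images]
    if missing:
        raise ValueError(f"images missing for ids: {missing}")
    refined_boxes: Dict[object, List[BoundingBox]] = {}
    rows = []
    for img_id in annotations.image_ids():
        image = images[img_id]
        refined_boxes[img_id] = []
        for k, box in enumerate(annotations.boxes[img_id]):
            res = refine_box(image, box, margin_frac=margin_frac, iters=iters,
                             backend=backend, classifier=classifier)
            refined_boxes[img_id].append(res.refined)
            rows.append({
                "image_id": img_id,
                "box_index": k,
                "iou_original_refined": _box_iou(res.original, res.refined),
                "converged": res.converged,
            })
    report = pd.DataFrame(rows, columns=["image_id", "box_index",
                                         "iou_original_refined", "converged"])
    return AnnotationSet(refined_boxes, categories=dict(annotations.categories)), report


class BoxRefiner(BaseEstimator):
    """Transformer-style wrapper: ``transform(annotations, images)`` returns
    the refined annotation set (report via :attr:`report_`)."""

    def __init__(self, margin_frac: float = 0.2, iters: int = 100,
                 backend: str = "contrast", classifier=None):
        self.margin_frac = margin_frac
        self.iters = iters
        self.backend = backend
        self.classifier = classifier

    def fit(self, X=None, y=None) -> "BoxRefiner":
        if self.backend == "cam" and self.classifier is None:
            raise ValueError("cam backend requires a classifier")
        return self

    def transform(self, annotations: AnnotationSet,
                  images: Dict[object, np.ndarray]) -> AnnotationSet:
        refined, report = refine_dataset(
            annotations, images, margin_frac=self.margin_frac,
            iters=self.iters, backend=self.backend, classifier=self.classifier)
        self.report_ = report
        return refined
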