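"""From-formula detection evaluation.

Implements the instance-level metrics used to score the detection stage —
IoU-gated greedy matching, interpolated average precision (101-point
precision-recall grid), mAP over the IoU threshold grid 0.50:0.05:0.95,
mAP50/mAP75, average recall — plus the image-level recall/precision/accuracy
used to score the occupancy filter, and ground-sample-distance stratified
reporting.

Conventions
-----------
* Matching is greedy per image: detections are visited in descending score
  order and each claims the unmatched ground-truth box of highest IoU,
  provided that IoU reaches the threshold; otherwise the detection is a
  false positive.  Ties on IoU break toward the lowest ground-truth index.
* AP sums the interpolated precision ``p(r) = max{precision at recall >= r}``
  over the recall grid ``r = 0, 0.01, ..., 1.00`` and divides by the 101 grid
  points, so AP lies in [0, 1].
* Detections are pooled across images into one ranked list per IoU
  threshold; average recall is the mean, over the IoU grid, of the final
  recall at each threshold (no max-detection cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AnnotationSet, BoundingBox, DetectionSet
from .core import iou as _box_iou

__all__ = [
    "BoundingBox",
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "ImageLevelMetrics",
    "iou",
    "match_detections",
    "average_precision",
    "evaluate",
    "image_level_metrics",
    "stratify_by_gsd",
    "default_iou_grid",
    "RECALL_GRID",
]

RECALL_GRID = np.round(np.arange(0, 101) * 0.01, 2)


def default_iou_grid() -> np.ndarray:
    """IoU thresholds 0.50 to 0.95 with step 0.05 (10 values)."""
    return np.round(np.arange(0.50, 0.951, 0.05), 2)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union; raises on degenerate input (enforced at
    construction of :class:`BoundingBox`)."""
    return _box_iou(a, b)


@dataclass
class MatchResult:
    """Outcome of matching one ranked detection list against ground truth.

    ``scores`` and ``is_tp`` are aligned and sorted by descending score;
    ``gt_matched`` flags which ground-truth boxes were claimed.
    """

    scores: np.ndarray
    is_tp: np.ndarray
    n_gt: int
    gt_matched: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int(len(self.is_tp) - self.is_tp.sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp

    @staticmethod
    def pooled(results: Sequence["MatchResult"]) -> "MatchResult":
        """Merge per-image results into one globally ranked list.

        Sorting is deterministic: descending score, then input order
        (stable mergesort).
        """
        if not results:
            return MatchResult(np.zeros(0), np.zeros(0, bool), 0)
        scores = np.concatenate([r.scores for r in results])
        is_tp = np.concatenate([r.is_tp for r in results])
        order = np.argsort(-scores, kind="stable")
        n_gt = sum(r.n_gt for r in results)
        return MatchResult(scores[order], is_tp[order], n_gt)


def match_detections(
    dets: Sequence[BoundingBox],
    gts: Sequence[BoundingBox],
    iou_thresh: float,
) -> MatchResult:
    """Greedy one-to-one matching of scored detections to ground truth."""
    if not (0 < iou_thresh <= 1):
        raise ValueError(f"iou_thresh must be in (0, 1], got {iou_thresh}")
    for d in dets:
        if d.score is None:
            raise ValueError("detections must carry scores")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    gt_matched = np.zeros(len(gts), dtype=bool)
    scores = np.array([dets[i].score for i in order], dtype=float)
    is_tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if gt_matched[j]:
                continue
            v = _box_iou(dets[i], g)
            if v > best_iou:  # strict > breaks IoU ties toward lowest gt index
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            is_tp[rank] = True
            gt_matched[best_j] = True
    return MatchResult(scores, is_tp, len(gts), gt_matched)


@dataclass
class PRCurve:
    """Interpolated precision at the 101-point recall grid."""

    recall_grid: np.ndarray
    precision: np.ndarray
    raw_recall: np.ndarray
    raw_precision: np.ndarray


def average_precision(matches: MatchResult, n_gt: Optional[int] = None
                      ) -> Tuple[Optional[float], PRCurve]:
    """Area under the interpolated precision-recall curve.

    With no ground truth but detections present, recall (hence AP) is
    undefined; ``None`` is returned rather than a silent zero.
    """
    if n_gt is None:
        n_gt = matches.n_gt
    if n_gt == 0:
        curve = PRCurve(RECALL_GRID, np.full(101, np.nan), np.zeros(0), np.zeros(0))
        return None, curve
    tp = np.cumsum(matches.is_tp.astype(float))
    fp = np.cumsum((~matches.is_tp).astype(float))
    denom = tp + fp
    precision = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
    recall = tp / n_gt
    # interpolated precision: max precision among operating points with
    # recall >= r, for each grid point r
    p_interp = np.zeros(101)
    if len(recall):
        # right-to-left running maximum of precision
        p_mono = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, RECALL_GRID, side="left")
        valid = idx < len(recall)
        p_interp[valid] = p_mono[idx[valid]]
    ap = float(p_interp.sum() / 101.0)
    return ap, PRCurve(RECALL_GRID, p_interp, recall, precision)


@dataclass
class ImageLevelMetrics:
    """Binary occupancy metrics; undefined ratios are ``None``."""

    recall: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]

    def __iter__(self):
        return iter((self.recall, self.precision, self.accuracy))


@dataclass
class EvalReport:
    """Instance-level metrics, optionally with image-level and per-GSD-bin
    sub-reports."""

    ap_by_iou: Dict[float, Optional[float]]
    mean_ap: Optional[float]
    map50: Optional[float]
    map75: Optional[float]
    average_recall: Optional[float]
    n_images: int = 0
    n_gt: int = 0
    n_det: int = 0
    image_level: Optional[ImageLevelMetrics] = None
    per_gsd_bin: Optional[Dict[str, "EvalReport"]] = None
    defined: bool = True

    def to_dict(self) -> dict:
        d = {
            "mAP": self.mean_ap,
            "mAP50": self.map50,
            "mAP75": self.map75,
            "AR": self.average_recall,
            "AP_by_iou": {f"{t:.2f}": v for t, v in self.ap_by_iou.items()},
            "n_images": self.n_images,
            "n_gt": self.n_gt,
            "n_det": self.n_det,
            "defined": self.defined,
        }
        if self.image_level is not None:
            d["image_level"] = {
                "R": self.image_level.recall,
                "P": self.image_level.precision,
                "Acc": self.image_level.accuracy,
            }
        if self.per_gsd_bin is not None:
            d["per_gsd_bin"] = {k: v.to_dict() for k, v in self.per_gsd_bin.items()}
        return d

    def to_frame(self) -> pd.DataFrame:
        """One-row table shaped like the standard mAP/mAP50/mAP75/AR report."""
        return pd.DataFrame(
            [{"mAP": self.mean_ap, "mAP50": self.map50,
              "mAP75": self.map75, "AR": self.average_recall}]
        )


def evaluate(
    dets: DetectionSet,
    gts: AnnotationSet,
    iou_grid: Optional[Sequence[float]] = None,
) -> EvalReport:
    """Full instance-level evaluation of a detection set against ground truth.

    Detections are matched per image at each IoU threshold, pooled into one
    ranked list, and summarised as AP per threshold, their mean (mAP),
    mAP50/mAP75, and average recall over the grid.
    """
    if iou_grid is None:
        iou_grid = default_iou_grid()
    iou_grid = [round(float(t), 2) for t in iou_grid]
    image_ids = sorted(set(gts.image_ids()) | set(dets.image_ids()), key=str)
    n_gt = gts.n_boxes()
    n_det = dets.n_boxes()

    ap_by_iou: Dict[float, Optional[float]] = {}
    recalls: List[float] = []
    for t in iou_grid:
        per_image = [
            match_detections(dets.boxes.get(i, []), gts.boxes.get(i, []), t)
            for i in image_ids
        ]
        pooled = MatchResult.pooled(per_image)
        ap, _ = average_precision(pooled)
        ap_by_iou[t] = ap
        if n_gt > 0:
            recalls.append(pooled.n_tp / n_gt)

    defined = n_gt > 0
    if defined:
        aps = [ap_by_iou[t] for t in iou_grid]
        mean_ap = float(np.mean(aps))
        ar = float(np.mean(recalls))
    else:
        mean_ap = ar = None
    return EvalReport(
        ap_by_iou=ap_by_iou,
        mean_ap=mean_ap,
        map50=ap_by_iou.get(0.5),
        map75=ap_by_iou.get(0.75),
        average_recall=ar,
        n_images=len(image_ids),
        n_gt=n_gt,
        n_det=n_det,
        defined=defined,
    )


def image_level_metrics(
    pred: Mapping[object, int], truth: Mapping[object, int]
) -> ImageLevelMetrics:
    """Recall, precision and accuracy of binary image-occupancy decisions.

    ``R = TP/(TP+FN)``, ``P = TP/(TP+FP)``, ``Acc = (TP+TN)/N``.
    """
    if set(pred) != set(truth):
        diff = set(pred) ^ set(truth)
        raise ValueError(f"image id mismatch between pred and truth: {sorted(map(str, diff))}")
    tp = fp = tn = fn = 0
    for k in pred:
        p, t = int(pred[k]), int(truth[k])
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    accuracy = (tp + tn) / n if n > 0 else None
    return ImageLevelMetrics(recall, precision, accuracy)


_BIN_NAMES = ("<{lo}", "{lo}-{hi}", ">{hi}")


def gsd_bin_of(gsd: float, bin_edges: Tuple[float, float] = (0.6, 1.2)) -> int:
    """Bin index for a ground-sample distance: 0 for ``< lo``, 1 for the
    closed middle interval ``[lo, hi]``, 2 for ``> hi``."""
    lo, hi = bin_edges
    if gsd < lo:
        return 0
    if gsd <= hi:
        return 1
    return 2


def stratify_by_gsd(
    dets: DetectionSet,
    gts: AnnotationSet,
    gsd_by_image: Mapping[object, float],
    bin_edges: Tuple[float, float] = (0.6, 1.2),
    iou_grid: Optional[Sequence[float]] = None,
) -> Dict[str, EvalReport]:
    """Evaluate separately within ground-sample-distance bins.

    Default bins follow the fine/medium/coarse split ``< 0.6``, ``0.6-1.2``
    and ``> 1.2`` cm/pixel, with both edges owned by the middle bin.  Bins
    containing no images yield flagged-null (not erroring) reports.
    """
    image_ids = sorted(set(gts.image_ids()) | set(dets.image_ids()), key=str)
    missing = [i for i in image_ids if i not in gsd_by_image]
    if missing:
        raise ValueError(f"missing GSD for image ids: {missing}")
    lo, hi = bin_edges
    names = [s.format(lo=lo, hi=hi) for s in _BIN_NAMES]
    out: Dict[str, EvalReport] = {}
    for b, name in enumerate(names):
        ids = [i for i in image_ids if gsd_bin_of(gsd_by_image[i], bin_edges) == b]
        sub_dets = DetectionSet({i: dets.boxes.get(i, []) for i in ids})
        sub_gts = AnnotationSet({i: gts.boxes.get(i, []) for i in ids},
                                categories=gts.categories)
        out[name] = evaluate(sub_dets, sub_gts, iou_grid=iou_grid)
    return out
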