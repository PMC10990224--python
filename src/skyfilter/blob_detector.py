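"""Classical detection baseline: contrast blobs + HOG features + linear SVM.

The chain mirrors the pre-deep-learning detector used as a baseline for
open-water bird surveys: the image is (optionally) contrast enhanced and
binarized at an intensity threshold (default 0.9, dark foreground on bright
water), the binary mask is dilated with a square structuring element
(default factor 12) so fragmented targets merge, connected components are
labeled with 8-pixel connectivity, each component's min/max pixel extents
become a bounding-box proposal, and a linear SVM over HOG features of each
proposal decides whether it contains a bird.

Because proposals are the extents of *dilated* blobs they are loose by the
dilation margin; :func:`detect` shrinks each proposal back by that margin
before scoring, which removes the systematic bias against tight ground
truth (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
from scipy.ndimage import maximum_filter
from skimage import exposure
from skimage.feature import hog as _sk_hog
from skimage.measure import label as _sk_label
from skimage.transform import resize as _resize
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from .core import BoundingBox, iou as _box_iou

__all__ = [
    "BlobParams",
    "HogParams",
    "ProposalSet",
    "ProposalClassifier",
    "binarize",
    "dilate",
    "connected_components",
    "proposals_from_components",
    "shrink_proposals",
    "hog_features",
    "train_svm",
    "detect",
    "BlobSvmDetector",
]


@dataclass(frozen=True)
class BlobParams:
    """Blob-proposal constants; defaults are the workflow's printed values
    (intensity threshold 0.9, dilation factor 12, 8-connectivity)."""

    intensity_threshold: float = 0.9
    dilation_factor: int = 12
    polarity: str = "dark_fg"
    contrast_enhance: str = "none"
    min_blob_px: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.intensity_threshold < 1):
            raise ValueError(
                f"intensity_threshold must be in (0, 1), got {self.intensity_threshold}")
        if self.dilation_factor < 0:
            raise ValueError(f"dilation_factor must be >= 0, got {self.dilation_factor}")
        if self.polarity not in ("dark_fg", "bright_fg"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.contrast_enhance not in ("none", "stretch", "clahe"):
            raise ValueError(f"unknown contrast_enhance {self.contrast_enhance!r}")


@dataclass(frozen=True)
class HogParams:
    """HOG descriptor geometry (standard 64x64 window / 8x8 cell / 2x2
    block / 9 orientations).  Block stride must equal the cell size (one
    cell), the stride scikit-image's HOG implements."""

    window: Tuple[int, int] = (64, 64)
    cell: Tuple[int, int] = (8, 8)
    block: Tuple[int, int] = (2, 2)
    block_stride: Tuple[int, int] = (8, 8)
    orientations: int = 9

    def __post_init__(self) -> None:
        ww, wh = self.window
        cw, ch = self.cell
        if ww % cw or wh % ch:
            raise ValueError(f"window {self.window} not divisible into cells {self.cell}")
        if self.block_stride != self.cell:
            raise ValueError(
                "block_stride must equal the cell size (one-cell stride)")
        if self.orientations <= 0:
            raise ValueError("orientations must be positive")

    @property
    def feature_length(self) -> int:
        nx = self.window[0] // self.cell[0] - self.block[0] + 1
        ny = self.window[1] // self.cell[1] - self.block[1] + 1
        return nx * ny * self.block[0] * self.block[1] * self.orientations


@dataclass
class ProposalSet:
    """Unscored box proposals, one per labeled blob, with pixel areas."""

    image_id: object
    boxes: List[BoundingBox] = field(default_factory=list)
    areas: List[int] = field(default_factory=list)

    def __len__(self):
        return len(self.boxes)


# ---------------------------------------------------------------------------
# stage operations


def _enhance(image: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return image
    if method == "stretch":
        p2, p98 = np.percentile(image, (2, 98))
        if p98 - p2 < 1e-9:
            return image
        return exposure.rescale_intensity(image, in_range=(p2, p98))
    if method == "clahe":
        return exposure.equalize_adapthist(np.clip(image, 0, 1))
    raise ValueError(f"unknown contrast_enhance {method!r}")


def binarize(image: np.ndarray, params: BlobParams) -> np.ndarray:
    """Threshold into a foreground mask after optional contrast enhancement.

    ``dark_fg`` marks pixels below the threshold; ``bright_fg`` marks pixels
    above ``1 - threshold``, so flipping polarity on the inverted image
    yields an identical mask.
    """
    enhanced = _enhance(np.asarray(image, dtype=float), params.contrast_enhance)
    if params.polarity == "dark_fg":
        return enhanced < params.intensity_threshold
    return enhanced > 1.0 - params.intensity_threshold


def dilate(mask: np.ndarray, dilation_factor: int) -> np.ndarray:
    """Morphological dilation with a square element of side
    ``dilation_factor`` (0 or 1 = identity)."""
    if dilation_factor < 0:
        raise ValueError(f"dilation_factor must be >= 0, got {dilation_factor}")
    if dilation_factor <= 1:
        return mask.astype(bool).copy()
    out = maximum_filter(mask.astype(np.uint8), size=dilation_factor)
    return out.astype(bool)


@lru_cache(maxsize=None)
def _dilation_margins(factor: int) -> Tuple[int, int]:
    """Per-side growth (low, high) that `dilate` adds to a blob extent.

    Probed empirically so the shrink correction matches the structuring
    element centering convention exactly.
    """
    if factor <= 1:
        return (0, 0)
    probe = np.zeros((4 * factor + 1, 4 * factor + 1), dtype=bool)
    c = 2 * factor
    probe[c, c] = True
    d = dilate(probe, factor)
    xs = np.nonzero(d[c])[0]
    return (c - int(xs.min()), int(xs.max()) - c)


def connected_components(mask: np.ndarray, connectivity: int = 8
                         ) -> Tuple[np.ndarray, int]:
    """Label foreground components; ids are contiguous from 1."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, count = _sk_label(mask.astype(bool),
                              connectivity=2 if connectivity == 8 else 1,
                              return_num=True)
    return labels, count


def proposals_from_components(labels: np.ndarray, min_blob_px: int = 1,
                              image_id: object = None) -> ProposalSet:
    """Tight box per labeled component with area >= ``min_blob_px``,
    ordered by (y0, x0)."""
    entries = []
    n = int(labels.max())
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        area = len(ys)
        if area == 0 or area < min_blob_px:
            continue
        box = BoundingBox(float(xs.min()), float(ys.min()),
                          float(xs.max() + 1), float(ys.max() + 1))
        entries.append((box.y0, box.x0, box, area))
    entries.sort(key=lambda e: (e[0], e[1]))
    return ProposalSet(image_id=image_id,
                       boxes=[e[2] for e in entries],
                       areas=[e[3] for e in entries])


def shrink_proposals(boxes: Sequence[BoundingBox], dilation_factor: int
                     ) -> List[BoundingBox]:
    """Undo the dilation margin on proposal extents (clamped to >= 2 px)."""
    lo, hi = _dilation_margins(dilation_factor)
    out = []
    for b in boxes:
        x0, x1 = b.x0 + lo, b.x1 - hi
        y0, y1 = b.y0 + lo, b.y1 - hi
        if x1 - x0 < 2:
            cx = 0.5 * (b.x0 + b.x1)
            x0, x1 = cx - 1, cx + 1
        if y1 - y0 < 2:
            cy = 0.5 * (b.y0 + b.y1)
            y0, y1 = cy - 1, cy + 1
        out.append(replace(b, x0=x0, y0=y0, x1=x1, y1=y1))
    return out


def _crop_box(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    h, w = image.shape[:2]
    x0 = int(np.clip(np.floor(box.x0), 0, w - 1))
    y0 = int(np.clip(np.floor(box.y0), 0, h - 1))
    x1 = int(np.clip(np.ceil(box.x1), x0 + 1, w))
    y1 = int(np.clip(np.ceil(box.y1), y0 + 1, h))
    return np.asarray(image, dtype=float)[y0:y1, x0:x1]


def hog_of_crop(crop: np.ndarray, params: HogParams) -> np.ndarray:
    """HOG descriptor of an already-extracted crop (resized to the HOG
    window, L2-Hys block normalization)."""
    ww, wh = params.window
    crop = _resize(crop, (wh, ww), order=1, anti_aliasing=False,
                   preserve_range=True)
    return _sk_hog(
        crop,
        orientations=params.orientations,
        pixels_per_cell=params.cell,
        cells_per_block=params.block,
        block_norm="L2-Hys",
        feature_vector=True,
    )


def hog_features(image: np.ndarray, box: BoundingBox, params: HogParams
                 ) -> np.ndarray:
    """HOG descriptor of a proposal: crop, resize to the HOG window, then
    histogram-of-oriented-gradients.  The feature length is fixed by the
    geometry, independent of box size."""
    return hog_of_crop(_crop_box(image, box), params)


# ---------------------------------------------------------------------------
# proposal classifier


@dataclass
class ProposalClassifier:
    """Linear SVM over HOG features; scores are the logistic of the SVM
    decision value so they are comparable across proposals (as NMS needs)."""

    svm: LinearSVC

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(np.atleast_2d(features))

    def scores(self, features: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_values(features)))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ProposalClassifier":
        return joblib.load(path)


def train_svm(pos_features: np.ndarray, neg_features: np.ndarray,
              c: float = 1.0, random_state: int = 0) -> ProposalClassifier:
    """Train the linear proposal classifier from positive/negative HOG
    feature matrices (at least one example per class)."""
    pos = np.atleast_2d(np.asarray(pos_features, dtype=float))
    neg = np.atleast_2d(np.asarray(neg_features, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one example per class to train the SVM")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    svm = LinearSVC(C=c, random_state=random_state)
    svm.fit(X, y)
    return ProposalClassifier(svm)


def detect(
    image: np.ndarray,
    blob_params: BlobParams,
    hog_params: HogParams,
    classifier: ProposalClassifier,
    score_threshold: float = 0.5,
) -> List[BoundingBox]:
    """Full chain: binarize, dilate, label components, propose boxes
    (margin-corrected), score with HOG+SVM, drop below the score
    threshold."""
    mask = binarize(image, blob_params)
    dilated = dilate(mask, blob_params.dilation_factor)
    labels, _ = connected_components(dilated, connectivity=8)
    props = proposals_from_components(labels, blob_params.min_blob_px)
    boxes = shrink_proposals(props.boxes, blob_params.dilation_factor)
    if not boxes:
        return []
    feats = np.stack([hog_features(image, b, hog_params) for b in boxes])
    scores = classifier.scores(feats)
    return [b.with_score(float(s)) for b, s in zip(boxes, scores)
            if s >= score_threshold]


# ---------------------------------------------------------------------------
# estimator


class BlobSvmDetector(BaseEstimator):
    """Scikit-learn-style estimator wrapping the blob + HOG + SVM chain.

    ``fit(X, y)`` takes a sequence of images and, aligned with it, a
    sequence of ground-truth box lists.  Proposals are generated on each
    training image and labeled positive iff their IoU with any ground-truth
    box reaches ``pos_iou`` (matching the evaluation's true-positive
    convention); when calm scenes yield fewer negative proposals than
    positives, additional negatives are sampled as random background boxes.
    ``predict(X)`` returns one scored box list per image.
    """

    def __init__(
        self,
        intensity_threshold: float = 0.9,
        dilation_factor: int = 12,
        polarity: str = "dark_fg",
        contrast_enhance: str = "none",
        min_blob_px: int = 4,
        hog_window: Tuple[int, int] = (64, 64),
        hog_cell: Tuple[int, int] = (8, 8),
        hog_block: Tuple[int, int] = (2, 2),
        hog_orientations: int = 9,
        C: float = 1.0,
        score_threshold: float = 0.5,
        pos_iou: float = 0.5,
        random_state: int = 0,
    ):
        self.intensity_threshold = intensity_threshold
        self.dilation_factor = dilation_factor
        self.polarity = polarity
        self.contrast_enhance = contrast_enhance
        self.min_blob_px = min_blob_px
        self.hog_window = hog_window
        self.hog_cell = hog_cell
        self.hog_block = hog_block
        self.hog_orientations = hog_orientations
        self.C = C
        self.score_threshold = score_threshold
        self.pos_iou = pos_iou
        self.random_state = random_state

    @property
    def blob_params_(self) -> BlobParams:
        return BlobParams(self.intensity_threshold, self.dilation_factor,
                          self.polarity, self.contrast_enhance, self.min_blob_px)

    @property
    def hog_params_(self) -> HogParams:
        return HogParams(tuple(self.hog_window), tuple(self.hog_cell),
                         tuple(self.hog_block), tuple(self.hog_cell),
                         self.hog_orientations)

    def _proposals(self, image: np.ndarray) -> List[BoundingBox]:
        mask = binarize(image, self.blob_params_)
        dilated = dilate(mask, self.dilation_factor)
        labels, _ = connected_components(dilated, connectivity=8)
        props = proposals_from_components(labels, self.min_blob_px)
        return shrink_proposals(props.boxes, self.dilation_factor)

    def _sample_background_boxes(self, image, gt_boxes, n, size, rng
                                 ) -> List[BoundingBox]:
        h, w = image.shape[:2]
        bw, bh = size
        out: List[BoundingBox] = []
        tries = 0
        while len(out) < n and tries < 50 * max(n, 1):
            tries += 1
            x0 = rng.uniform(0, max(w - bw, 1))
            y0 = rng.uniform(0, max(h - bh, 1))
            cand = BoundingBox(x0, y0, min(x0 + bw, w), min(y0 + bh, h))
            if all(_box_iou(cand, g) < 0.1 for g in gt_boxes):
                out.append(cand)
        return out

    def fit(self, X: Sequence[np.ndarray],
            y: Sequence[Sequence[BoundingBox]]) -> "BlobSvmDetector":
        if len(X) != len(y):
            raise ValueError("X and y must align")
        rng = np.random.default_rng(self.random_state)
        hog_p = self.hog_params_
        pos_feats, neg_feats = [], []
        gt_sizes = []
        for image, gts in zip(X, y):
            proposals = self._proposals(image)
            for b in proposals:
                best = max((_box_iou(b, g) for g in gts), default=0.0)
                feats = hog_features(image, b, hog_p)
                (pos_feats if best >= self.pos_iou else neg_feats).append(feats)
            # annotated boxes are positives in their own right; flips and
            # quarter-turns of each crop widen the pose coverage beyond
            # what a small number of annotated birds gives
            for g in gts:
                crop = _crop_box(image, g)
                for variant in (crop, crop[:, ::-1], crop[::-1, :],
                                crop.T, crop[::-1, ::-1]):
                    pos_feats.append(hog_of_crop(variant, hog_p))
            gt_sizes.extend((g.width, g.height) for g in gts)
        if len(pos_feats) == 0:
            raise ValueError("no positive proposals found; cannot train")
        if len(neg_feats) < max(5, len(pos_feats)):
            # calm water yields no clutter proposals; fill in with random
            # background boxes so the classifier sees both classes
            size = (float(np.median([s[0] for s in gt_sizes])),
                    float(np.median([s[1] for s in gt_sizes])))
            need = max(5, len(pos_feats)) - len(neg_feats)
            per_img = int(np.ceil(need / max(len(X), 1)))
            for image, gts in zip(X, y):
                for b in self._sample_background_boxes(image, list(gts),
                                                       per_img, size, rng):
                    neg_feats.append(hog_features(image, b, hog_p))
        self.classifier_ = train_svm(np.stack(pos_feats), np.stack(neg_feats),
                                     c=self.C, random_state=self.random_state)
        self.n_features_in_ = hog_p.feature_length
        return self

    def predict_image(self, image: np.ndarray) -> List[BoundingBox]:
        if not hasattr(self, "classifier_"):
            raise ValueError("detector is not fitted")
        return detect(image, self.blob_params_, self.hog_params_,
                      self.classifier_, self.score_threshold)

    def predict(self, X: Sequence[np.ndarray]) -> List[List[BoundingBox]]:
        return [self.predict_image(img) for img in X]
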