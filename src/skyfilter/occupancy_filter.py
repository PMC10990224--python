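"""Stage-1 occupancy filtering: does this image contain any bird?

Large survey collections are mostly empty water; filtering parent frames by
the probability of bird occurrence before running detection is what makes
an in-flight workflow tractable.  Patches are classified individually and
aggregated to the parent frame: the parent probability is the max over its
patches, whose thresholded version is exactly the any-patch OR rule.

Two backends:

``proposal_heuristic``
    Needs no training — a patch is occupied iff the blob detector yields at
    least one proposal; the probability is a smooth function of the
    proposal count (``1 - exp(-n)``, 0 for empty patches).

``small_cnn``
    A compact convolutional classifier: a fixed convolutional feature bank
    (difference-of-Gaussian blob channels at three scales, two gradient
    channels, and one seeded-random 3x3 mixing convolution), global average
    pooling, and a single trained fully-connected (logistic) layer.  The
    GAP + FC structure makes a class-activation map available to the box
    refiner (:func:`SmallConvNetFilter.feature_maps` /
    :attr:`SmallConvNetFilter.class_weights_`).  Training is deterministic
    given the seed and takes seconds on one CPU.

The data-augmentation recipe for training patches follows the standard
random-resized-crop scheme: crop area 0.08-1.0 of the source, aspect jitter
in [3/4, 4/3], resize to 480x480, horizontal flip with probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import correlate as _nd_correlate
from scipy.ndimage import gaussian_filter, gaussian_gradient_magnitude
from skimage.measure import block_reduce
from skimage.transform import resize as _resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .blob_detector import (BlobParams, binarize, connected_components,
                            dilate, proposals_from_components)
from .core import BoundingBox, ParentImage
from .tiler import extract_patch, plan_tiles

__all__ = [
    "AugmentSpec",
    "augment_patch",
    "make_patch_dataset",
    "ProposalHeuristicFilter",
    "SmallConvNetFilter",
    "train_filter",
    "predict_patch",
    "filter_images",
]


@dataclass(frozen=True)
class AugmentSpec:
    """Random-resized-crop augmentation recipe (defaults: area 0.08-1.0 of
    the source patch, output 480x480, horizontal flip with p=0.5)."""

    crop_area_range: Tuple[float, float] = (0.08, 1.0)
    out_size: Tuple[int, int] = (480, 480)
    hflip_prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.crop_area_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"crop_area_range must lie in (0, 1], got {self.crop_area_range}")
        if not (0 <= self.hflip_prob <= 1):
            raise ValueError(f"hflip_prob must be in [0, 1], got {self.hflip_prob}")


def augment_patch(
    patch: np.ndarray,
    spec: AugmentSpec,
    seed: int,
    gt_boxes: Optional[Sequence[BoundingBox]] = None,
) -> Tuple[np.ndarray, Optional[int]]:
    """One random-resized-crop augmentation of a training patch.

    Returns the augmented patch and, when ``gt_boxes`` (in patch
    coordinates) are given, its occupancy label: positive iff the crop
    window contains at least one ground-truth box center.  Deterministic
    given the seed.
    """
    h, w = patch.shape[:2]
    if h < 32 or w < 32:
        raise ValueError(f"patch too small to augment: {w}x{h}")
    rng = np.random.default_rng(seed)
    crop = None
    for _ in range(10):
        area = rng.uniform(*spec.crop_area_range) * h * w
        aspect = np.exp(rng.uniform(np.log(3 / 4), np.log(4 / 3)))
        cw = int(round(np.sqrt(area * aspect)))
        ch = int(round(np.sqrt(area / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            x0 = int(rng.integers(0, w - cw + 1))
            y0 = int(rng.integers(0, h - ch + 1))
            crop = (x0, y0, cw, ch)
            break
    if crop is None:
        crop = (0, 0, w, h)  # fallback: full-window resize
    x0, y0, cw, ch = crop
    out_w, out_h = spec.out_size
    sub = patch[y0:y0 + ch, x0:x0 + cw]
    aug = _resize(sub, (out_h, out_w), order=1, anti_aliasing=False,
                  preserve_range=True)
    if rng.uniform() < spec.hflip_prob:
        aug = aug[:, ::-1].copy()
    label = None
    if gt_boxes is not None:
        label = int(any(
            x0 <= b.center[0] < x0 + cw and y0 <= b.center[1] < y0 + ch
            for b in gt_boxes
        ))
    return aug, label


def make_patch_dataset(
    images: Sequence[np.ndarray],
    gt_boxes_per_image: Sequence[Sequence[BoundingBox]],
    window: int = 720,
    stride: int = 540,
    n_augments: int = 2,
    spec: Optional[AugmentSpec] = None,
    seed: int = 0,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Tile images with the training grid and emit augmented labeled
    patches for filter training."""
    if spec is None:
        spec = AugmentSpec()
    patches, labels = [], []
    counter = 0
    for image, gts in zip(images, gt_boxes_per_image):
        h, w = image.shape[:2]
        grid = plan_tiles(w, h, (window, window), (stride, stride))
        for tile in grid:
            patch = extract_patch(image, tile)
            local = [b.translated(-tile.x_off, -tile.y_off) for b in gts]
            for _ in range(n_augments):
                aug, lab = augment_patch(patch, spec, seed=seed + counter,
                                         gt_boxes=local)
                patches.append(aug)
                labels.append(lab)
                counter += 1
    return patches, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# backends


class ProposalHeuristicFilter(BaseEstimator, ClassifierMixin):
    """Training-free occupancy backend driven by blob proposals.

    ``p = 1 - exp(-n)`` where ``n`` is the number of blob proposals passing
    the minimum-area filter; an empty patch maps to exactly 0.
    """

    def __init__(self, intensity_threshold: float = 0.9,
                 dilation_factor: int = 12, polarity: str = "dark_fg",
                 contrast_enhance: str = "none", min_blob_px: int = 4):
        self.intensity_threshold = intensity_threshold
        self.dilation_factor = dilation_factor
        self.polarity = polarity
        self.contrast_enhance = contrast_enhance
        self.min_blob_px = min_blob_px

    def fit(self, X=None, y=None) -> "ProposalHeuristicFilter":
        self.fitted_ = True
        return self

    def _count(self, patch: np.ndarray) -> int:
        params = BlobParams(self.intensity_threshold, self.dilation_factor,
                            self.polarity, self.contrast_enhance,
                            self.min_blob_px)
        mask = binarize(patch, params)
        labels, _ = connected_components(dilate(mask, self.dilation_factor))
        return len(proposals_from_components(labels, self.min_blob_px))

    def predict_proba(self, X: Sequence[np.ndarray]) -> np.ndarray:
        p1 = np.array([1.0 - np.exp(-self._count(p)) for p in X])
        return np.column_stack([1 - p1, p1])

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class SmallConvNetFilter(BaseEstimator, ClassifierMixin):
    """Compact convolutional occupancy classifier with a GAP + FC head.

    The convolutional stack (fixed analytic filters plus one seeded-random
    mixing layer) is frozen; only the fully-connected logistic layer is
    trained, which keeps training deterministic and CPU-cheap while
    preserving the class-activation-map structure.
    """

    def __init__(self, input_size: int = 160,
                 dog_sigmas: Tuple[float, ...] = (1.5, 3.0, 6.0),
                 n_mix: int = 16, pool: int = 4, C: float = 1.0,
                 random_state: int = 0):
        self.input_size = input_size
        self.dog_sigmas = dog_sigmas
        self.n_mix = n_mix
        self.pool = pool
        self.C = C
        self.random_state = random_state

    # -- frozen convolutional stack ------------------------------------
    def _mix_kernels(self) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        n_in = 2 * len(self.dog_sigmas) + 2
        k = rng.standard_normal((self.n_mix, n_in, 3, 3))
        return k / np.sqrt((k ** 2).sum(axis=(1, 2, 3), keepdims=True))

    def feature_maps(self, patch: np.ndarray) -> np.ndarray:
        """Spatial feature maps ``(h', w', n_mix)`` for one patch; the
        tensor the class-activation map is built from."""
        s = self.input_size
        x = _resize(np.asarray(patch, dtype=float), (s, s), order=1,
                    anti_aliasing=True, preserve_range=True)
        chans = []
        for sig in self.dog_sigmas:
            d = gaussian_filter(x, sig) - gaussian_filter(x, 2 * sig)
            chans.append(np.maximum(d, 0))
            chans.append(np.maximum(-d, 0))
        for sig in self.dog_sigmas[:2]:
            chans.append(gaussian_gradient_magnitude(x, sig))
        bank = np.stack(
            [block_reduce(c, (self.pool, self.pool), np.max) for c in chans],
            axis=0)
        kernels = self._mix_kernels() if not hasattr(self, "kernels_") else self.kernels_
        mixed = [
            np.maximum(
                sum(_nd_correlate(bank[c], kernels[m, c], mode="nearest")
                    for c in range(bank.shape[0])),
                0)
            for m in range(kernels.shape[0])
        ]
        return np.stack(mixed, axis=-1)

    def _gap_features(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return np.stack([self.feature_maps(p).mean(axis=(0, 1)) for p in X])

    # -- estimator API --------------------------------------------------
    def fit(self, X: Sequence[np.ndarray], y) -> "SmallConvNetFilter":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("filter training needs both classes present")
        self.kernels_ = self._mix_kernels()
        feats = self._gap_features(X)
        self.scaler_ = StandardScaler().fit(feats)
        self.logreg_ = LogisticRegression(C=self.C, max_iter=2000,
                                          random_state=self.random_state)
        self.logreg_.fit(self.scaler_.transform(feats), y)
        self.classes_ = self.logreg_.classes_
        return self

    @property
    def class_weights_(self) -> np.ndarray:
        """Per-channel weights of the positive class on the (unscaled)
        feature maps; with :func:`feature_maps` this yields the CAM."""
        return self.logreg_.coef_[0] / self.scaler_.scale_

    def predict_proba(self, X: Sequence[np.ndarray]) -> np.ndarray:
        if not hasattr(self, "logreg_"):
            raise ValueError("filter model is not fitted")
        feats = self.scaler_.transform(self._gap_features(X))
        return self.logreg_.predict_proba(feats)

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_filter(patches: Sequence[np.ndarray], labels,
                 backend: str = "small_cnn", **params):
    """Train (or construct) a filter model for the requested backend."""
    if backend == "proposal_heuristic":
        return ProposalHeuristicFilter(**params).fit()
    if backend == "small_cnn":
        return SmallConvNetFilter(**params).fit(patches, labels)
    raise ValueError(f"unknown filter backend {backend!r}")


def predict_patch(model, patch: np.ndarray) -> float:
    """Probability that one patch contains a bird."""
    return float(model.predict_proba([patch])[0, 1])


def filter_images(
    model,
    parents: Sequence[ParentImage],
    window: int = 1440,
    stride: int = 1080,
    rescale: Optional[int] = 960,
    threshold: float = 0.5,
) -> Tuple[List[object], List[object], pd.DataFrame]:
    """Stage-1 decision over parent frames.

    Each parent is tiled with the inference grid, every patch is scored,
    and the parent probability is the max over patches; the parent is kept
    iff that probability exceeds the threshold.  Every parent appears in
    the returned table regardless of the decision.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    kept, dropped, rows = [], [], []
    for parent in parents:
        h, w = parent.image.shape[:2]
        grid = plan_tiles(w, h, (window, window), (stride, stride),
                          parent_id=parent.image_id)
        probs = []
        for tile in grid:
            if rescale is not None:
                # scale the rescale target with any border clamping so the
                # effective downscale factor matches the configured one
                tw = max(32, int(round(tile.window_w * rescale / window)))
                th = max(32, int(round(tile.window_h * rescale / window)))
                patch = extract_patch(parent.image, tile, rescale_to=(tw, th))
            else:
                patch = extract_patch(parent.image, tile)
            probs.append(predict_patch(model, patch))
        p = float(max(probs))
        decision = int(p > threshold)
        (kept if decision else dropped).append(parent.image_id)
        rows.append({"image_id": parent.image_id, "p_occurrence": p,
                     "decision": decision})
    table = pd.DataFrame(rows, columns=["image_id", "p_occurrence", "decision"])
    return kept, dropped, table
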