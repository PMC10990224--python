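"""Synthetic open-water aerial scenes with known ground truth.

Every other stage of the workflow is exercised against scenes produced
here: a bright water background with band-limited wave texture and
saturated glare patches, dark compact bird targets whose pixel footprint
scales inversely with the ground-sample distance (GSD, cm/pixel), and
tight ground-truth boxes recorded at stamp time.  A separate operation
manufactures *loose* (padded) boxes that stand in for manual annotations,
which the box refiner must tighten.

The generator is deliberately simple: birds are flat-shaded ellipses with
mild intensity jitter, because at survey GSDs the detectors operate on
contrast blobs, not plumage.  All randomness is driven by the scene seed,
so identical specs produce identical scenes, files and annotations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import BoundingBox, iou as _box_iou

__all__ = [
    "SceneSpec",
    "BirdTarget",
    "SyntheticScene",
    "generate_background",
    "place_birds",
    "generate_scene",
    "loosen_boxes",
    "generate_dataset",
]

# intensity model constants: sunlit water sits near the bright end with
# bounded wave texture; glare saturates.
_BASE_INTENSITY = 0.94
_WAVE_AMPLITUDE = 0.12      # at sea_state = 1
_BACKGROUND_CEIL = 0.985    # non-glare background stays below saturation
_SATURATION = 1.0
_BIRD_JITTER_SD = 0.02


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``gsd_cm`` is the ground-sample distance in cm/pixel; the bird pixel
    footprint (major axis) is ``bird_length_cm / gsd_cm`` rounded, floored
    at 2 px.  ``bird_contrast`` is the intensity gap between background
    mean and bird body; ``sea_state`` scales the wave-texture amplitude;
    ``glare_fraction`` is the fraction of pixels driven to saturation.
    """

    width_px: int
    height_px: int
    gsd_cm: float = 0.3
    n_birds: int = 0
    bird_length_cm: float = 40.0
    bird_contrast: float = 0.5
    sea_state: float = 0.15
    glare_fraction: float = 0.0
    seed: int = 0
    polarity: str = "dark_fg"
    min_separation_px: int = 16

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(f"non-positive scene dimensions {self.width_px}x{self.height_px}")
        if self.gsd_cm <= 0:
            raise ValueError(f"gsd_cm must be positive, got {self.gsd_cm}")
        if self.n_birds < 0:
            raise ValueError(f"n_birds must be non-negative, got {self.n_birds}")
        if self.bird_length_cm <= 0:
            raise ValueError(f"bird_length_cm must be positive, got {self.bird_length_cm}")
        if not (0 < self.bird_contrast <= 1):
            raise ValueError(f"bird_contrast must be in (0, 1], got {self.bird_contrast}")
        if not (0 <= self.sea_state <= 1):
            raise ValueError(f"sea_state must be in [0, 1], got {self.sea_state}")
        if not (0 <= self.glare_fraction <= 1):
            raise ValueError(f"glare_fraction must be in [0, 1], got {self.glare_fraction}")
        if self.polarity not in ("dark_fg", "bright_fg"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be non-negative")

    @property
    def footprint_px(self) -> int:
        """Bird major-axis length in pixels (>= 2)."""
        return max(2, int(round(self.bird_length_cm / self.gsd_cm)))


@dataclass(frozen=True)
class BirdTarget:
    """Stamp-time metadata of one placed bird."""

    cx: float
    cy: float
    major_px: float
    axis_ratio: float
    theta: float
    box: BoundingBox


@dataclass
class SyntheticScene:
    image: np.ndarray
    gt_boxes: List[BoundingBox]
    spec: SceneSpec
    birds: List[BirdTarget] = field(default_factory=list)
    fg_mask: Optional[np.ndarray] = None


def _bounded_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited noise normalized to [-1, 1]."""
    n = gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(n).max()
    return n / peak if peak > 0 else n


def generate_background(spec: SceneSpec) -> np.ndarray:
    """Bright water background with wave texture and glare.

    Wave texture is the sum of a fine and a broad band-limited noise field,
    bounded so that with ``sea_state <= 0.2`` the background never crosses
    the blob detector's default 0.9 threshold.  Glare patches are placed by
    thresholding a low-frequency field at the ``1 - glare_fraction``
    quantile and saturating, so the saturated fraction tracks
    ``glare_fraction`` by construction.
    """
    if spec.width_px < 64 or spec.height_px < 64:
        raise ValueError("scene dimensions must be at least 64x64")
    shape = (spec.height_px, spec.width_px)
    rng = np.random.default_rng([spec.seed, 0])
    img = np.full(shape, _BASE_INTENSITY, dtype=float)
    if spec.sea_state > 0:
        fine = _bounded_noise(rng, shape, sigma=3.0)
        broad = _bounded_noise(rng, shape, sigma=16.0)
        img += _WAVE_AMPLITUDE * spec.sea_state * (0.6 * fine + 0.4 * broad)
        img = np.clip(img, 0.0, _BACKGROUND_CEIL)
    if spec.glare_fraction > 0:
        glare_field = gaussian_filter(rng.standard_normal(shape), sigma=24.0)
        if spec.glare_fraction >= 1:
            img[:] = _SATURATION
        else:
            thr = np.quantile(glare_field, 1.0 - spec.glare_fraction)
            img[glare_field >= thr] = _SATURATION
    if spec.polarity == "bright_fg":
        img = 1.0 - img
    return img


def _stamp_ellipse(rng, shape, cx, cy, a, b, theta) -> np.ndarray:
    """Boolean mask of a rotated ellipse with semi-axes a, b."""
    h, w = shape
    half = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _box_gap(a: BoundingBox, b: BoundingBox) -> float:
    """Largest axis gap between two boxes (0 if they touch or overlap)."""
    hgap = max(b.x0 - a.x1, a.x0 - b.x1)
    vgap = max(b.y0 - a.y1, a.y0 - b.y1)
    return max(hgap, vgap, 0.0)


def place_birds(background: np.ndarray, spec: SceneSpec) -> SyntheticScene:
    """Stamp dark elliptical bird targets into a background.

    Each bird has major axis ``spec.footprint_px``, axis ratio drawn from
    [0.35, 0.65], random orientation, and body intensity
    ``background mean - bird_contrast`` with mild per-pixel jitter.
    Placement is rejection-sampled (up to 50 tries per bird) against a
    pairwise ground-truth IoU cap of 0.1 and a minimum box separation of
    ``spec.min_separation_px`` (keeps neighbouring ground truth
    unambiguous); birds that cannot be placed are dropped, and the returned
    boxes reflect the birds actually stamped.
    """
    h, w = background.shape[:2]
    major = spec.footprint_px
    if spec.n_birds > 0 and major >= min(h, w):
        raise ValueError(
            f"bird footprint {major}px does not fit in {w}x{h} scene"
        )
    rng = np.random.default_rng([spec.seed, 1])
    img = background.astype(float).copy()
    bg_mean = float(np.mean(background))
    sign = 1.0 if spec.polarity == "bright_fg" else -1.0
    body = float(np.clip(bg_mean + sign * spec.bird_contrast, 0.02, 0.98))

    boxes: List[BirdTarget] = []
    fg_mask = np.zeros((h, w), dtype=bool)
    margin = major / 2 + 2
    for _ in range(spec.n_birds):
        placed = None
        for _try in range(50):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            ratio = rng.uniform(0.35, 0.65)
            theta = rng.uniform(0, np.pi)
            a, b = major / 2.0, major * ratio / 2.0
            mask = _stamp_ellipse(rng, (h, w), cx, cy, a, b, theta)
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            box = BoundingBox(float(xs.min()), float(ys.min()),
                              float(xs.max() + 1), float(ys.max() + 1))
            ok = all(
                _box_iou(box, t.box) <= 0.1
                and _box_gap(box, t.box) >= spec.min_separation_px
                for t in boxes
            )
            if ok:
                placed = (mask, box, ratio, theta, cx, cy)
                break
        if placed is None:
            continue
        mask, box, ratio, theta, cx, cy = placed
        jitter = rng.normal(0.0, _BIRD_JITTER_SD, size=int(mask.sum()))
        img[mask] = np.clip(body + jitter, 0.0, 1.0)
        fg_mask |= mask
        boxes.append(BirdTarget(cx, cy, float(major), ratio, theta, box))

    return SyntheticScene(
        image=img,
        gt_boxes=[t.box for t in boxes],
        spec=spec,
        birds=boxes,
        fg_mask=fg_mask,
    )


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Convenience: background + birds in one call."""
    return place_birds(generate_background(spec), spec)


def loosen_boxes(
    gt_boxes: Sequence[BoundingBox],
    pad_frac_range: Tuple[float, float],
    seed: int,
    image_size: Optional[Tuple[int, int]] = None,
) -> List[BoundingBox]:
    """Expand boxes by independent per-side random pads, emulating loose
    manual annotations.

    Each side moves outward by ``u * side_length`` with ``u`` drawn
    uniformly from ``pad_frac_range`` (width for the x sides, height for
    the y sides).  Output order matches input.  If ``image_size=(w, h)`` is
    given, boxes are clipped to the image bounds.
    """
    lo, hi = pad_frac_range
    if lo < 0 or hi < 0 or lo > hi:
        raise ValueError(f"invalid pad_frac_range {pad_frac_range}")
    rng = np.random.default_rng(seed)
    out: List[BoundingBox] = []
    for b in gt_boxes:
        pads = rng.uniform(lo, hi, size=4)
        loose = replace(
            b,
            x0=b.x0 - pads[0] * b.width,
            x1=b.x1 + pads[1] * b.width,
            y0=b.y0 - pads[2] * b.height,
            y1=b.y1 + pads[3] * b.height,
        )
        if image_size is not None:
            loose = loose.clipped(image_size[0], image_size[1])
        out.append(loose)
    return out


def _coco_dict(scene_boxes, sizes, file_names) -> dict:
    images, annotations = [], []
    ann_id = 1
    for img_id, boxes in scene_boxes.items():
        w, h = sizes[img_id]
        images.append({"id": img_id, "file_name": file_names[img_id],
                       "width": w, "height": h})
        for b in boxes:
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": 1,
                "bbox": [round(v, 3) for v in b.to_xywh()],
                "area": round(b.area, 3),
                "iscrowd": 0,
            })
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "bird"}],
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n")


def generate_dataset(
    specs: Sequence[SceneSpec],
    out_dir,
    splits: Optional[Sequence[str]] = None,
    loosen_range: Tuple[float, float] = (0.2, 0.4),
) -> pd.DataFrame:
    """Render scenes to disk as a small survey dataset.

    Writes 8-bit PNG images, a COCO-style JSON with tight boxes
    (``annotations_tight.json``), a second JSON with loosened boxes
    (``annotations_loose.json``), and a CSV manifest with columns
    ``image_id,file_name,gsd_cm,split,n_birds``.  No timestamps are
    recorded, so regeneration from the same specs is byte-identical.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out_dir}: {e}") from e
    if splits is None:
        splits = ["train"] * len(specs)
    if len(splits) != len(specs):
        raise ValueError("splits must match specs in length")

    tight, loose, sizes, file_names, rows = {}, {}, {}, {}, []
    for i, (spec, split) in enumerate(zip(specs, splits)):
        scene = generate_scene(spec)
        img_id = i
        fname = f"scene_{i:04d}.png"
        arr = np.clip(np.round(scene.image * 255), 0, 255).astype(np.uint8)
        try:
            iio.imwrite(img_dir / fname, arr)
        except OSError as e:
            raise OSError(f"failed writing image {img_dir / fname}: {e}") from e
        tight[img_id] = scene.gt_boxes
        loose[img_id] = loosen_boxes(
            scene.gt_boxes, loosen_range, seed=spec.seed + 7,
            image_size=(spec.width_px, spec.height_px))
        sizes[img_id] = (spec.width_px, spec.height_px)
        file_names[img_id] = fname
        rows.append({
            "image_id": img_id,
            "file_name": fname,
            "gsd_cm": spec.gsd_cm,
            "split": split,
            "n_birds": len(scene.gt_boxes),
        })

    _write_json(_coco_dict(tight, sizes, file_names), out_dir / "annotations_tight.json")
    _write_json(_coco_dict(loose, sizes, file_names), out_dir / "annotations_loose.json")
    manifest = pd.DataFrame(rows, columns=["image_id", "file_name", "gsd_cm",
                                           "split", "n_birds"])
    manifest.to_csv(out_dir / "manifest.csv", index=False,
                    quoting=csv.QUOTE_MINIMAL)
    return manifest
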