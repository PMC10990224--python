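"""Sliding-window decomposition of large survey frames.

Parent frames (80-megapixel camera frames in the motivating surveys) are too
large to process whole, so they are cropped into overlapping windows:
720x720 with stride 540 for training, 1440x1440 with stride 1080 (optionally
rescaled to 960x960) for inference.  This module plans those grids, maps
boxes between patch and parent coordinates, aggregates patch-level occupancy
labels to a parent-level decision, and merges per-tile detections with
greedy non-maximum suppression so birds straddling tile overlaps are not
double-counted.

Edge policy: the final window on each axis is clamped to the frame border
(never padded, never dropped), so every parent pixel is covered and no
synthetic pixels are introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _resize

from .core import BoundingBox, iou as _box_iou

__all__ = [
    "Tile",
    "TileGrid",
    "plan_tiles",
    "extract_patch",
    "patch_to_parent",
    "aggregate_occupancy",
    "greedy_nms",
    "merge_detections",
]


@dataclass(frozen=True)
class Tile:
    """One window of a parent frame: offsets and size in parent pixels."""

    x_off: int
    y_off: int
    window_w: int
    window_h: int
    parent_id: object = None


@dataclass
class TileGrid:
    parent_w: int
    parent_h: int
    window: Tuple[int, int]
    stride: Tuple[int, int]
    tiles: List[Tile]

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self):
        return len(self.tiles)


def _axis_origins(parent: int, window: int, stride: int) -> List[int]:
    if parent <= window:
        return [0]
    k = math.ceil((parent - window) / stride) + 1
    origins = [min(i * stride, parent - window) for i in range(k)]
    return origins


def plan_tiles(
    parent_w: int,
    parent_h: int,
    window: Tuple[int, int],
    stride: Tuple[int, int],
    parent_id: object = None,
) -> TileGrid:
    """Plan a clamped sliding-window grid covering every parent pixel.

    Per axis, origins sit at ``k * stride`` with the last origin clamped to
    ``parent - window``; ``K = ceil((parent - window) / stride) + 1``.  When
    the window exceeds the parent dimension a single tile clamped to the
    parent is produced.
    """
    ww, wh = window
    sw, sh = stride
    if sw <= 0 or sh <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if ww <= 0 or wh <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if sw > ww or sh > wh:
        raise ValueError(f"stride {stride} must not exceed window {window}")
    eff_w, eff_h = min(ww, parent_w), min(wh, parent_h)
    xs = _axis_origins(parent_w, eff_w, sw)
    ys = _axis_origins(parent_h, eff_h, sh)
    tiles = [Tile(x, y, eff_w, eff_h, parent_id) for y in ys for x in xs]
    return TileGrid(parent_w, parent_h, window, stride, tiles)


def extract_patch(
    image: np.ndarray,
    tile: Tile,
    rescale_to: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Pixel-exact crop of a tile, with optional bilinear rescale."""
    h, w = image.shape[:2]
    if (tile.x_off < 0 or tile.y_off < 0
            or tile.x_off + tile.window_w > w or tile.y_off + tile.window_h > h):
        raise ValueError(f"tile {tile} outside image of size {w}x{h}")
    patch = image[tile.y_off:tile.y_off + tile.window_h,
                  tile.x_off:tile.x_off + tile.window_w]
    if rescale_to is not None:
        tw, th = rescale_to
        out_shape = (th, tw) + patch.shape[2:]
        patch = _resize(patch, out_shape, order=1, anti_aliasing=False,
                        preserve_range=True).astype(patch.dtype, copy=False)
    return patch


def patch_to_parent(
    box: BoundingBox,
    tile: Tile,
    rescale_from: Optional[Tuple[int, int]] = None,
) -> BoundingBox:
    """Map a box from tile (possibly rescaled-patch) coordinates to the
    parent frame, preserving score and label."""
    if rescale_from is not None:
        rw, rh = rescale_from
        box = box.scaled(tile.window_w / rw, tile.window_h / rh)
    return box.translated(tile.x_off, tile.y_off)


def aggregate_occupancy(patch_labels: Sequence[int]) -> int:
    """Parent-level occupancy: logical OR over patch labels — if any patch
    contains an object the parent image does."""
    if len(patch_labels) == 0:
        raise ValueError("a parent image with no patches is malformed")
    return int(any(int(v) == 1 for v in patch_labels))


def greedy_nms(boxes: Sequence[BoundingBox], nms_iou: float) -> List[BoundingBox]:
    """Greedy non-maximum suppression.

    Boxes sorted by descending score (ties broken by x0 then y0); a box is
    kept iff its IoU with every already-kept box is strictly below
    ``nms_iou``.
    """
    if not (0 < nms_iou < 1):
        raise ValueError(f"nms_iou must be in (0, 1), got {nms_iou}")
    order = sorted(boxes, key=lambda b: (-(b.score or 0.0), b.x0, b.y0))
    kept: List[BoundingBox] = []
    for b in order:
        if all(_box_iou(b, k) < nms_iou for k in kept):
            kept.append(b)
    return kept


def merge_detections(
    per_tile_dets: Sequence[Tuple[Tile, Sequence[BoundingBox]]],
    nms_iou: float = 0.5,
    rescale_from: Optional[Tuple[int, int]] = None,
) -> List[BoundingBox]:
    """Map per-tile detections to parent coordinates and suppress
    cross-tile duplicates with greedy NMS."""
    mapped = [
        patch_to_parent(b, tile, rescale_from=rescale_from)
        for tile, dets in per_tile_dets
        for b in dets
    ]
    return greedy_nms(mapped, nms_iou)
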