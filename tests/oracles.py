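"""Independent reference implementations used only by the tests.

Everything here is deliberately naive (explicit loops, no shared code with
the package) so it can serve as an oracle for the vectorised
implementations under test.
"""

from collections import deque


# ---------------------------------------------------------------------------
# box arithmetic on plain (x0, y0, x1, y1) tuples


def iou_tuple(a, b):
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


# ---------------------------------------------------------------------------
# naive ranked precision-recall sweep


def brute_force_ap(dets_by_image, gts_by_image, thr):
    """AP at one IoU threshold via an explicit greedy sweep.

    ``dets_by_image``: image id -> list of (score, box tuple);
    ``gts_by_image``: image id -> list of box tuples.  Returns
    (ap, final_recall); ap is None when no ground truth exists.
    """
    records = []
    total_gt = 0
    for iid in set(dets_by_image) | set(gts_by_image):
        ds = sorted(dets_by_image.get(iid, []), key=lambda t: -t[0])
        gs = list(gts_by_image.get(iid, []))
        used = [False] * len(gs)
        total_gt += len(gs)
        for score, box in ds:
            best_iou, best_j = 0.0, -1
            for j, g in enumerate(gs):
                if used[j]:
                    continue
                v = iou_tuple(box, g)
                if v > best_iou:
                    best_iou, best_j = v, j
            tp = best_j >= 0 and best_iou >= thr
            if tp:
                used[best_j] = True
            records.append((score, tp))
    if total_gt == 0:
        return None, None
    records.sort(key=lambda t: -t[0])
    points = []
    tp = fp = 0
    for _, is_tp in records:
        tp += 1 if is_tp else 0
        fp += 0 if is_tp else 1
        points.append((tp / total_gt, tp / (tp + fp)))
    ap = 0.0
    for k in range(101):
        r = k / 100.0
        ap += max((p for rec, p in points if rec >= r - 1e-12), default=0.0)
    final_recall = tp / total_gt
    return ap / 101.0, final_recall


# ---------------------------------------------------------------------------
# second, COCO-protocol-style accumulator (vector-free)


def coco_style_ap(dets_by_image, gts_by_image, thr):
    """AP via the standard COCO accumulation protocol: global score sort,
    cumulative TP/FP, monotone precision envelope, precision sampled at the
    first operating point whose recall reaches each of the 101 grid values."""
    records = []
    total_gt = 0
    for iid in sorted(set(dets_by_image) | set(gts_by_image), key=str):
        ds = sorted(dets_by_image.get(iid, []), key=lambda t: -t[0])
        gs = list(gts_by_image.get(iid, []))
        used = [False] * len(gs)
        total_gt += len(gs)
        for score, box in ds:
            best_iou, best_j = 0.0, -1
            for j, g in enumerate(gs):
                if not used[j]:
                    v = iou_tuple(box, g)
                    if v > best_iou:
                        best_iou, best_j = v, j
            tp = best_j >= 0 and best_iou >= thr
            if tp:
                used[best_j] = True
            records.append((score, tp))
    if total_gt == 0:
        return None
    records.sort(key=lambda t: -t[0])
    tps, n = [], 0
    for _, t in records:
        n += 1 if t else 0
        tps.append(n)
    recall = [t / total_gt for t in tps]
    precision = [t / (i + 1) for i, t in enumerate(tps)]
    # monotone non-increasing precision envelope, right to left
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    q = []
    for k in range(101):
        r = k / 100.0
        idx = next((i for i, rc in enumerate(recall) if rc >= r - 1e-12), None)
        q.append(precision[idx] if idx is not None else 0.0)
    return sum(q) / 101.0


# ---------------------------------------------------------------------------
# flood-fill connected components


def flood_fill_count(mask, connectivity=8):
    """Number of foreground components by BFS flood fill."""
    h = len(mask)
    w = len(mask[0]) if h else 0
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = [[False] * w for _ in range(h)]
    count = 0
    for y in range(h):
        for x in range(w):
            if not mask[y][x] or seen[y][x]:
                continue
            count += 1
            queue = deque([(y, x)])
            seen[y][x] = True
            while queue:
                cy, cx = queue.popleft()
                for dy, dx in steps:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w \
                            and mask[ny][nx] and not seen[ny][nx]:
                        seen[ny][nx] = True
                        queue.append((ny, nx))
    return count


def random_instance(rng, max_boxes=20, n_images=3):
    """A random detection/ground-truth problem for oracle comparison."""
    dets, gts = {}, {}
    for iid in range(n_images):
        n_gt = int(rng.integers(0, max_boxes + 1))
        n_det = int(rng.integers(0, max_boxes + 1))
        boxes = []
        for _ in range(n_gt):
            x0, y0 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(4, 20, 2)
            boxes.append((x0, y0, x0 + w, y0 + h))
        gts[iid] = boxes
        dboxes = []
        for _ in range(n_det):
            if boxes and rng.uniform() < 0.7:
                bx = boxes[int(rng.integers(0, len(boxes)))]
                jit = rng.uniform(-4, 4, 4)
                cand = (bx[0] + jit[0], bx[1] + jit[1],
                        bx[2] + jit[2], bx[3] + jit[3])
                if cand[2] - cand[0] < 1 or cand[3] - cand[1] < 1:
                    continue
            else:
                x0, y0 = rng.uniform(0, 80, 2)
                w, h = rng.uniform(4, 20, 2)
                cand = (x0, y0, x0 + w, y0 + h)
            dboxes.append((float(rng.uniform()), cand))
        dets[iid] = dboxes
    return dets, gts
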