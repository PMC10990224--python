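"""Unit and property tests for the detection-evaluation suite."""

import numpy as np
import pytest
from oracles import brute_force_ap, coco_style_ap, iou_tuple, random_instance

from skyfilter.core import AnnotationSet, BoundingBox, DetectionSet
from skyfilter.detect_eval import (MatchResult, average_precision,
                                   default_iou_grid, evaluate, gsd_bin_of,
                                   image_level_metrics, iou,
                                   match_detections, stratify_by_gsd)


def B(x0, y0, x1, y1, score=None):
    return BoundingBox(x0, y0, x1, y1, score=score)


def _to_sets(dets_by_image, gts_by_image):
    dets = DetectionSet({
        i: [B(*b, score=s) for s, b in ds] for i, ds in dets_by_image.items()
    })
    gts = AnnotationSet({i: [B(*b) for b in gs]
                         for i, gs in gts_by_image.items()})
    return dets, gts


class TestIou:
    def test_identical_boxes(self):
        assert iou(B(0, 0, 10, 10), B(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(B(0, 0, 10, 10), B(20, 20, 30, 30)) == 0.0

    def test_half_overlap(self):
        # intersection 50, union 150
        assert iou(B(0, 0, 10, 10), B(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetric(self):
        a, b = B(0, 0, 10, 10), B(3, 4, 12, 9)
        assert iou(a, b) == iou(b, a)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            B(5, 5, 5, 10)

    def test_matches_direct_arithmetic_on_random_integer_boxes(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a = rng.integers(0, 20, 2)
            b = rng.integers(0, 20, 2)
            wa, ha, wb, hb = rng.integers(1, 15, 4)
            ta = (a[0], a[1], a[0] + wa, a[1] + ha)
            tb = (b[0], b[1], b[0] + wb, b[1] + hb)
            assert iou(B(*ta), B(*tb)) == pytest.approx(iou_tuple(ta, tb),
                                                        abs=1e-12)


class TestMatching:
    def test_exact_single_match(self):
        m = match_detections([B(0, 0, 10, 10, 0.9)], [B(0, 0, 10, 10)], 0.95)
        assert m.n_tp == 1 and m.n_fp == 0 and m.n_fn == 0

    def test_one_gt_claimed_once(self):
        dets = [B(0, 0, 10, 10, 0.9), B(1, 0, 11, 10, 0.8)]
        m = match_detections(dets, [B(0, 0, 10, 10)], 0.5)
        assert m.n_tp == 1 and m.n_fp == 1
        assert m.is_tp[0] and not m.is_tp[1]  # the higher score wins the gt

    def test_threshold_semantics_at_iou_half(self):
        det = B(0, 0, 10, 5, 0.9)  # IoU exactly 0.5 with the gt
        gt = B(0, 0, 10, 10)
        assert iou(det, gt) == 0.5
        assert match_detections([det], [gt], 0.5).n_tp == 1
        assert match_detections([det], [gt], 0.75).n_tp == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestAveragePrecision:
    def test_single_true_positive(self):
        m = match_detections([B(0, 0, 10, 10, 0.9)], [B(0, 0, 10, 10)], 0.5)
        ap, _ = average_precision(m)
        assert ap == pytest.approx(1.0)

    def test_single_false_positive(self):
        m = match_detections([B(50, 50, 60, 60, 0.9)], [B(0, 0, 10, 10)], 0.5)
        ap, _ = average_precision(m)
        assert ap == pytest.approx(0.0)

    def test_tp_then_fp_interpolates_to_one(self):
        dets = [B(0, 0, 10, 10, 0.9), B(50, 50, 60, 60, 0.5)]
        m = match_detections(dets, [B(0, 0, 10, 10)], 0.5)
        ap, curve = average_precision(m)
        assert ap == pytest.approx(1.0)
        assert np.all(np.diff(curve.precision) <= 1e-12)

    def test_no_ground_truth_is_flagged_null(self):
        m = match_detections([B(0, 0, 10, 10, 0.9)], [], 0.5)
        ap, _ = average_precision(m)
        assert ap is None

    def test_interpolated_precision_non_increasing(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            dets_bi, gts_bi = random_instance(rng)
            dets, gts = _to_sets(dets_bi, gts_bi)
            ids = sorted(set(dets.boxes) | set(gts.boxes))
            pooled = MatchResult.pooled([
                match_detections(dets.boxes.get(i, []), gts.boxes.get(i, []), 0.5)
                for i in ids])
            ap, curve = average_precision(pooled)
            if ap is not None:
                assert np.all(np.diff(curve.precision) <= 1e-12)
                assert np.all((curve.precision >= 0) & (curve.precision <= 1))


class TestEvaluate:
    def test_perfect_detections_score_one(self):
        gts = {0: [(0, 0, 10, 10), (30, 30, 45, 40)], 1: [(5, 5, 20, 25)]}
        dets = {i: [(0.9, b) for b in bs] for i, bs in gts.items()}
        d, g = _to_sets(dets, gts)
        rep = evaluate(d, g)
        assert rep.mean_ap == rep.map50 == rep.map75 == rep.average_recall == 1.0

    def test_default_grid_has_ten_thresholds(self):
        assert len(default_iou_grid()) == 10
        assert default_iou_grid()[0] == 0.50 and default_iou_grid()[-1] == 0.95

    def test_map_is_mean_of_per_threshold_aps(self):
        rng = np.random.default_rng(7)
        dets_bi, gts_bi = random_instance(rng)
        d, g = _to_sets(dets_bi, gts_bi)
        rep = evaluate(d, g)
        if rep.defined:
            assert rep.mean_ap == pytest.approx(
                np.mean(list(rep.ap_by_iou.values())), abs=1e-12)

    def test_ap_monotone_in_iou_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dets_bi, gts_bi = random_instance(rng)
            d, g = _to_sets(dets_bi, gts_bi)
            rep = evaluate(d, g)
            if rep.defined:
                aps = [rep.ap_by_iou[t] for t in sorted(rep.ap_by_iou)]
                assert np.all(np.diff(aps) <= 1e-12)

    def test_no_ground_truth_anywhere_flagged(self):
        d, g = _to_sets({0: [(0.9, (0, 0, 10, 10))]}, {0: []})
        rep = evaluate(d, g)
        assert not rep.defined and rep.mean_ap is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            dets_bi, gts_bi = random_instance(rng)
            d, g = _to_sets(dets_bi, gts_bi)
            rep = evaluate(d, g, iou_grid=[0.5, 0.75])
            for t in (0.5, 0.75):
                expect, _ = brute_force_ap(dets_bi, gts_bi, t)
                if expect is None:
                    assert not rep.defined
                else:
                    assert rep.ap_by_iou[t] == pytest.approx(expect, abs=1e-9)


class TestImageLevelMetrics:
    def test_perfect_prediction(self):
        m = image_level_metrics({0: 1, 1: 0}, {0: 1, 1: 0})
        assert tuple(m) == (1.0, 1.0, 1.0)

    def test_mixed_confusion(self):
        pred = {0: 1, 1: 0, 2: 1, 3: 0}
        truth = {0: 1, 1: 1, 2: 0, 3: 0}
        assert tuple(image_level_metrics(pred, truth)) == (0.5, 0.5, 0.5)

    def test_all_negative_pred_has_null_precision(self):
        m = image_level_metrics({0: 0, 1: 0}, {0: 1, 1: 0})
        assert m.recall == 0.0 and m.precision is None

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            image_level_metrics({0: 1}, {1: 1})


class TestGsdStratification:
    def _simple_sets(self, ids):
        gts = AnnotationSet({i: [B(0, 0, 10, 10)] for i in ids})
        dets = DetectionSet({i: [B(0, 0, 10, 10, 0.9)] for i in ids})
        return dets, gts

    def test_one_image_per_bin(self):
        dets, gts = self._simple_sets([0, 1, 2])
        out = stratify_by_gsd(dets, gts, {0: 0.3, 1: 0.8, 2: 1.5})
        assert [r.n_images for r in out.values()] == [1, 1, 1]

    def test_empty_bins_are_reported_not_errors(self):
        dets, gts = self._simple_sets([0, 1])
        out = stratify_by_gsd(dets, gts, {0: 0.3, 1: 0.4})
        reports = list(out.values())
        assert reports[0].n_images == 2
        assert reports[1].n_images == 0 and not reports[1].defined

    def test_missing_gsd_listed(self):
        dets, gts = self._simple_sets([0, 1])
        with pytest.raises(ValueError, match="missing GSD"):
            stratify_by_gsd(dets, gts, {0: 0.3})

    def test_bin_membership_matches_interval_oracle(self):
        rng = np.random.default_rng(5)
        lo, hi = 0.6, 1.2
        for g in rng.uniform(0.05, 2.0, 100):
            expect = 0 if g < lo else (1 if g <= hi else 2)
            assert gsd_bin_of(float(g), (lo, hi)) == expect

    def test_edges_belong_to_middle_bin(self):
        assert gsd_bin_of(0.6) == 1 and gsd_bin_of(1.2) == 1
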