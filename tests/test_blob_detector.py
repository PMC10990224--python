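"""Tests for the blob-proposal + HOG + SVM detection baseline."""

import numpy as np
import pytest
from oracles import flood_fill_count

from skyfilter.blob_detector import (BlobParams, BlobSvmDetector, HogParams,
                                     ProposalClassifier, binarize,
                                     connected_components, detect, dilate,
                                     hog_features, proposals_from_components,
                                     shrink_proposals, train_svm)
from skyfilter.core import AnnotationSet, BoundingBox, DetectionSet, iou
from skyfilter.detect_eval import evaluate, match_detections
from skyfilter.synthetic import SceneSpec, generate_scene


class TestBinarize:
    def test_constant_bright_image_yields_empty_mask(self):
        img = np.ones((32, 32))
        assert not binarize(img, BlobParams()).any()

    def test_polarity_flip_on_inverted_image_is_identical(self):
        scene = generate_scene(SceneSpec(256, 256, n_birds=3, seed=2))
        dark = binarize(scene.image, BlobParams(polarity="dark_fg"))
        bright = binarize(1.0 - scene.image, BlobParams(polarity="bright_fg"))
        assert np.array_equal(dark, bright)

    def test_bird_pixels_foreground_with_stretch(self):
        scene = generate_scene(SceneSpec(512, 512, n_birds=5,
                                         bird_contrast=0.4, seed=3))
        mask = binarize(scene.image, BlobParams(contrast_enhance="stretch"))
        assert mask[scene.fg_mask].mean() >= 0.95

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            BlobParams(intensity_threshold=1.5)


class TestDilate:
    def test_factor_zero_is_identity(self):
        mask = np.random.default_rng(0).uniform(size=(20, 20)) > 0.8
        assert np.array_equal(dilate(mask, 0), mask)

    def test_single_pixel_becomes_square_block(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 20] = True
        out = dilate(mask, 12)
        assert out.sum() == 144
        ys, xs = np.nonzero(out)
        assert ys.max() - ys.min() == 11 and xs.max() - xs.min() == 11

    def test_block_clipped_at_border(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, 0] = True
        out = dilate(mask, 12)
        assert 0 < out.sum() < 144

    def test_monotone_superset(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mask = rng.uniform(size=(24, 24)) > 0.85
            out = dilate(mask, int(rng.integers(2, 9)))
            assert (out | mask).sum() == out.sum()

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            dilate(np.zeros((4, 4), bool), -1)


class TestConnectedComponents:
    def test_empty_mask(self):
        _, n = connected_components(np.zeros((8, 8), bool))
        assert n == 0

    def test_diagonal_touch_distinguishes_connectivity(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = True  # touch only diagonally
        _, n8 = connected_components(mask, connectivity=8)
        _, n4 = connected_components(mask, connectivity=4)
        assert (n8, n4) == (1, 2)

    def test_ids_contiguous_from_one(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1], mask[5, 5], mask[8, 2] = True, True, True
        labels, n = connected_components(mask)
        assert n == 3
        assert sorted(np.unique(labels)) == [0, 1, 2, 3]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_counts_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(200):
            mask = rng.uniform(size=(32, 32)) > 0.7
            _, n = connected_components(mask, connectivity=connectivity)
            assert n == flood_fill_count(mask.tolist(), connectivity)


class TestProposals:
    def test_rectangle_blob_extents(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[10:13, 20:25] = 1  # 5 wide x 3 tall at (x=20, y=10)
        props = proposals_from_components(labels)
        assert len(props) == 1
        b = props.boxes[0]
        assert (b.x0, b.y0, b.x1, b.y1) == (20, 10, 25, 13)
        assert props.areas == [15]

    def test_small_blob_filtered(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2, 2] = 1
        labels[10:14, 10:14] = 2
        props = proposals_from_components(labels, min_blob_px=4)
        assert len(props) == 1 and props.areas == [16]

    def test_count_equals_components_without_filter(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(32, 32)) > 0.85
        labels, n = connected_components(mask)
        assert len(proposals_from_components(labels, min_blob_px=1)) == n

    def test_order_deterministic_by_position(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[15:17, 1:3] = 1
        labels[1:3, 15:17] = 2
        props = proposals_from_components(labels)
        assert props.boxes[0].y0 < props.boxes[1].y0


class TestShrinkProposals:
    def test_recovers_pre_dilation_extent(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:30, 25:40] = True
        labels, _ = connected_components(dilate(mask, 12))
        props = proposals_from_components(labels)
        (b,) = shrink_proposals(props.boxes, 12)
        assert (b.x0, b.y0, b.x1, b.y1) == (25, 20, 40, 30)


class TestHog:
    def test_feature_length_from_geometry(self):
        params = HogParams()
        assert params.feature_length == 7 * 7 * 4 * 9  # 1764
        img = generate_scene(SceneSpec(256, 256, n_birds=1, seed=1)).image
        feats = hog_features(img, BoundingBox(10, 10, 80, 60), params)
        assert feats.shape == (1764,)

    def test_constant_crop_has_negligible_gradients(self):
        img = np.full((64, 64), 0.5)
        feats = hog_features(img, BoundingBox(0, 0, 64, 64), HogParams())
        assert np.abs(feats).max() < 1e-9

    def test_length_independent_of_box_size(self):
        img = generate_scene(SceneSpec(256, 256, n_birds=2, seed=5)).image
        small = hog_features(img, BoundingBox(5, 5, 20, 20), HogParams())
        large = hog_features(img, BoundingBox(5, 5, 200, 180), HogParams())
        assert small.shape == large.shape

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            HogParams(window=(60, 60), cell=(8, 8))


class TestSvm:
    def test_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(3, 0.1, size=(20, 4))
        neg = rng.normal(-3, 0.1, size=(20, 4))
        clf = train_svm(pos, neg, c=1.0)
        assert (clf.scores(pos) > 0.5).all() and (clf.scores(neg) < 0.5).all()

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        clf = train_svm(rng.normal(1, 1, (10, 4)), rng.normal(-1, 1, (10, 4)))
        clf.save(tmp_path / "svm.joblib")
        loaded = ProposalClassifier.load(tmp_path / "svm.joblib")
        X = rng.normal(size=(5, 4))
        assert np.array_equal(clf.decision_values(X), loaded.decision_values(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.ones((3, 4)), np.empty((0, 4)))

    def test_heldout_proposal_accuracy(self, trained_detector):
        """The trained proposal classifier separates bird proposals from
        background boxes on held-out scenes."""
        correct = total = 0
        for seed in (300, 301):
            scene = generate_scene(SceneSpec(720, 720, gsd_cm=0.3, n_birds=4,
                                             seed=seed))
            boxes = trained_detector._proposals(scene.image)
            extra = trained_detector._sample_background_boxes(
                scene.image, scene.gt_boxes, 4, (100, 60),
                np.random.default_rng(seed))
            for b in boxes + extra:
                truth = max((iou(b, g) for g in scene.gt_boxes), default=0) >= 0.5
                feats = hog_features(scene.image, b,
                                     trained_detector.hog_params_)
                pred = trained_detector.classifier_.scores(feats)[0] >= 0.5
                correct += pred == truth
                total += 1
        assert total >= 10 and correct / total >= 0.9


class TestDetect:
    def test_water_only_scene_yields_nothing(self, trained_detector):
        scene = generate_scene(SceneSpec(720, 720, gsd_cm=0.3, n_birds=0,
                                         seed=88))
        assert trained_detector.predict_image(scene.image) == []

    def test_easy_scene_recovers_birds(self, trained_detector):
        scene = generate_scene(SceneSpec(1024, 1024, gsd_cm=0.3, n_birds=10,
                                         seed=90))
        dets = trained_detector.predict_image(scene.image)
        m = match_detections(dets, scene.gt_boxes, 0.5)
        assert m.n_tp >= 9

    def test_deterministic(self, trained_detector):
        scene = generate_scene(SceneSpec(512, 512, gsd_cm=0.3, n_birds=3,
                                         seed=91))
        a = trained_detector.predict_image(scene.image)
        b = trained_detector.predict_image(scene.image)
        assert a == b

    def test_dilation_merges_nearby_fragments(self, trained_detector):
        """A bird split into two fragments closer than the dilation factor
        produces a single proposal."""
        img = np.full((128, 128), 0.95)
        img[60:70, 40:58] = 0.4   # fragment 1
        img[60:70, 64:80] = 0.4   # fragment 2, 6 px gap < 12
        boxes = trained_detector._proposals(img)
        assert len(boxes) == 1

    def test_classifier_adds_precision_over_keeping_all_proposals(self):
        """On cluttered seas the learned classifier must beat the
        no-classifier variant (all proposals kept) on mAP."""
        def spec(seed, n):
            return SceneSpec(640, 640, gsd_cm=0.5, n_birds=n,
                             bird_contrast=0.5, sea_state=0.75, seed=seed)
        train = [generate_scene(spec(s, 4)) for s in range(6)]
        det = BlobSvmDetector(random_state=0)
        det.fit([s.image for s in train], [s.gt_boxes for s in train])
        test = [generate_scene(spec(400 + s, 4)) for s in range(4)]
        gts = AnnotationSet({i: s.gt_boxes for i, s in enumerate(test)})
        with_svm = DetectionSet(
            {i: det.predict_image(s.image) for i, s in enumerate(test)})
        all_props = DetectionSet({
            i: [b.with_score(1.0) for b in det._proposals(s.image)]
            for i, s in enumerate(test)})
        map_svm = evaluate(with_svm, gts).mean_ap
        map_all = evaluate(all_props, gts).mean_ap
        assert map_svm > map_all

    def test_unfitted_detector_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            BlobSvmDetector().predict_image(np.ones((64, 64)))

    def test_functional_chain_matches_estimator(self, trained_detector):
        scene = generate_scene(SceneSpec(512, 512, gsd_cm=0.3, n_birds=3,
                                         seed=92))
        direct = detect(scene.image, trained_detector.blob_params_,
                        trained_detector.hog_params_,
                        trained_detector.classifier_)
        assert direct == trained_detector.predict_image(scene.image)
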