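import numpy as np
import pytest

from conftest import random_boxes
from equinodes.detector import (
    AnchorSpec,
    DetectorModel,
    TrainingConfig,
    assign_training_targets,
    build_anchor_grid,
    decode_offsets,
    detect,
    encode_offsets,
    iou,
    iou_matrix,
    suppress_overlaps,
    train_detector,
)
from equinodes.synthetic import PAPER_COLOR, SyntheticParams, generate_specimen
from equinodes.types import BoundingBox, Detection, NodeType, TaxonLabel, ValidationError


def det(x0, y0, x1, y1, score, t=NodeType.H):
    return Detection(BoundingBox(x0, y0, x1, y1), t, score)


class TestAnchorGrid:
    def test_default_spec_has_36_anchors_per_point(self):
        spec = AnchorSpec()
        assert spec.anchors_per_point == 36
        anchors = build_anchor_grid(90, spec)
        assert anchors.shape == (9 * 36, 4)

    def test_grid_point_arithmetic(self):
        spec = AnchorSpec(pitch=30, sizes=(30.0,), aspect_ratios=(1.0,))
        anchors = build_anchor_grid(90, spec)
        assert anchors.shape == (9, 4)
        centers = np.stack(
            [(anchors[:, 0] + anchors[:, 2]) / 2, (anchors[:, 1] + anchors[:, 3]) / 2], axis=1
        )
        expected = [[x, y] for y in (15, 45, 75) for x in (15, 45, 75)]
        assert centers.tolist() == expected

    def test_anchors_clipped_to_image(self):
        anchors = build_anchor_grid(60, AnchorSpec(pitch=30))
        assert anchors.min() >= 0
        assert anchors.max() <= 60
        assert (anchors[:, 2] > anchors[:, 0]).all()

    def test_image_below_pitch_rejected(self):
        with pytest.raises(ValidationError):
            build_anchor_grid(20, AnchorSpec(pitch=30))

    def test_count_formula_for_rectangular_image(self):
        spec = AnchorSpec(pitch=30, sizes=(30.0, 60.0), aspect_ratios=(0.5, 1.0, 2.0))
        anchors = build_anchor_grid((90, 150), spec)
        assert anchors.shape[0] == 3 * 5 * 6


class TestIoU:
    def test_identity_disjoint_and_partial(self):
        a = BoundingBox(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, BoundingBox(5, 5, 7, 7)) == 0.0
        assert iou(a, BoundingBox(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        A, B = random_boxes(rng, 12), random_boxes(rng, 7)
        m = iou_matrix(A, B)
        for i in range(12):
            for j in range(7):
                assert m[i, j] == pytest.approx(iou(BoundingBox(*A[i]), BoundingBox(*B[j])))


def greedy_nms_oracle(detections, threshold):
    """Literal re-statement of the suppression rule for cross-checking."""
    from equinodes.detector import iou as _iou

    order = sorted(
        detections, key=lambda d: (-d.score, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)
    )
    kept = []
    for d in order:
        if all(_iou(d.box, k.box) <= threshold for k in kept):
            kept.append(d)
    return kept


class TestSuppressOverlaps:
    def test_higher_score_wins(self):
        a = det(0, 0, 10, 10, 0.9)
        b = det(1, 0, 11, 10, 0.7)  # IoU with a > 0.5
        assert iou(a.box, b.box) > 0.5
        assert suppress_overlaps([a, b], 0.5) == [a]

    def test_disjoint_all_kept(self):
        ds = [det(i * 20, 0, i * 20 + 10, 10, 0.5 + i * 0.01) for i in range(5)]
        assert len(suppress_overlaps(ds, 0.5)) == 5

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(120):
            n = int(rng.integers(1, 50))
            boxes = random_boxes(rng, n, extent=60)
            scores = np.round(rng.uniform(0, 1, n), 3)  # rounded -> some ties
            ds = [
                det(*b, s, NodeType.L if rng.random() < 0.5 else NodeType.H)
                for b, s in zip(boxes, scores)
            ]
            thr = float(rng.uniform(0.1, 0.7))
            assert suppress_overlaps(ds, thr) == greedy_nms_oracle(ds, thr)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        boxes = random_boxes(rng, 25, extent=50)
        ds = [det(*b, float(s)) for b, s in zip(boxes, rng.uniform(0, 1, 25))]
        ref = suppress_overlaps(ds, 0.4)
        for _ in range(5):
            perm = list(rng.permutation(len(ds)))
            assert suppress_overlaps([ds[i] for i in perm], 0.4) == ref


class TestAssignTargets:
    def test_no_ground_truth_all_background(self):
        anchors = build_anchor_grid(90, AnchorSpec())
        labels, offsets = assign_training_targets(anchors, np.zeros((0, 4)), np.zeros(0, dtype=int))
        assert (labels == 0).all()
        assert (offsets == 0).all()

    def test_exact_anchor_match_zero_offsets(self):
        anchors = build_anchor_grid(90, AnchorSpec(pitch=30, sizes=(30.0,), aspect_ratios=(1.0,)))
        gt = anchors[4:5].copy()
        labels, offsets = assign_training_targets(anchors, gt, np.array([2]))
        assert labels[4] == 2
        assert np.allclose(offsets[4], 0.0)

    def test_best_iou_matching_agrees_with_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            anchors = random_boxes(rng, 20, extent=80)
            gt = random_boxes(rng, int(rng.integers(1, 6)), extent=80)
            gt_labels = rng.integers(1, 3, size=gt.shape[0])
            thr = 0.4
            labels, offsets = assign_training_targets(anchors, gt, gt_labels, thr)

            m = np.array([[iou(BoundingBox(*a), BoundingBox(*g)) for g in gt] for a in anchors])
            expected_pos = set(np.nonzero(m.max(axis=1) >= thr)[0]) | set(m.argmax(axis=0))
            assert set(np.nonzero(labels > 0)[0]) == expected_pos
            # anchors positive by threshold (and not force-claimed) carry the
            # label of their best-IoU ground truth
            forced = m.argmax(axis=0)
            for i in expected_pos:
                if i not in forced:
                    assert labels[i] == gt_labels[m[i].argmax()]

    def test_offset_encoding_round_trip(self):
        rng = np.random.default_rng(3)
        anchors = random_boxes(rng, 30, extent=100)
        gt = random_boxes(rng, 30, extent=100)
        decoded = decode_offsets(anchors, encode_offsets(anchors, gt))
        assert np.allclose(decoded, gt, atol=1e-9)


class TestTrainingAndDetection:
    def test_training_reaches_low_validation_error(self, trained_model):
        model, history = trained_model
        first_error = history["val_error"][0][1]
        assert history["best_val_error"] < 0.15
        assert history["best_val_error"] < first_error

    def test_same_seed_same_loss_trajectory(self, small_dataset):
        images, _ = small_dataset
        pure = [i for i in images if i.taxon != TaxonLabel.FERRISSII]
        cfg = TrainingConfig(max_iterations=60, eval_every=30)
        _, h1 = train_detector(pure[:4], pure[4:6], cfg, seed=2)
        _, h2 = train_detector(pure[:4], pure[4:6], cfg, seed=2)
        assert h1["loss"] == h2["loss"]

    def test_empty_train_rejected(self, small_dataset):
        images, _ = small_dataset
        with pytest.raises(ValidationError):
            train_detector([], images[:2], TrainingConfig())

    def test_blank_background_yields_no_detections(self, trained_model):
        model, _ = trained_model
        rng = np.random.default_rng(0)
        blank = np.clip(
            PAPER_COLOR + rng.normal(0, 4, (400, 400, 3)), 0, 255
        ).astype(np.uint8)
        assert detect(model, blank) == []

    def test_detection_postconditions(self, small_dataset, trained_model):
        from equinodes.detector import iou as _iou

        images, _ = small_dataset
        model, _ = trained_model
        img = next(i for i in images if i.taxon is TaxonLabel.LAEVIGATUM)
        dets = detect(model, img.image, overlap_threshold=0.3)
        assert dets
        h, w = img.image.shape[:2]
        for d in dets:
            assert 0.0 <= d.score <= 1.0
            assert 0 <= d.box.x_min < d.box.x_max <= w
        for i in range(len(dets)):
            for j in range(i + 1, len(dets)):
                assert _iou(dets[i].box, dets[j].box) <= 0.3 + 1e-9

    def test_majority_type_on_pure_image(self, small_dataset, trained_model):
        images, _ = small_dataset
        model, _ = trained_model
        img = next(i for i in images if i.taxon is TaxonLabel.LAEVIGATUM)
        dets = detect(model, img.image)
        l_count = sum(d.node_type is NodeType.L for d in dets)
        assert l_count > len(dets) / 2

    def test_score_threshold_monotonicity(self, small_dataset, trained_model):
        images, _ = small_dataset
        model, _ = trained_model
        img = images[0]
        low = detect(model, img.image, score_threshold=0.2)
        high = detect(model, img.image, score_threshold=0.6)
        assert len(high) <= len(low)
        # every high-threshold survivor scored >= 0.6
        assert all(d.score >= 0.6 for d in high)

    def test_untrained_model_rejected(self):
        with pytest.raises(ValidationError):
            detect(DetectorModel(), np.zeros((100, 100, 3), dtype=np.uint8))

    def test_save_load_bit_identical_inference(self, tmp_path, small_dataset, trained_model):
        images, _ = small_dataset
        model, _ = trained_model
        model.save(tmp_path / "det")
        loaded = DetectorModel.load(tmp_path / "det")
        img = images[3].image
        assert detect(model, img) == detect(loaded, img)
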