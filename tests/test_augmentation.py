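import numpy as np
import pytest

from equinodes.augmentation import (
    AugmentationConfig,
    augment,
    random_crop,
    rotate_image_and_boxes,
)
from equinodes.synthetic import SyntheticParams, generate_specimen
from equinodes.types import AnnotationBox, BoundingBox, Category, TaxonLabel


def ann(x0, y0, x1, y1):
    return AnnotationBox(BoundingBox(x0, y0, x1, y1), Category.NORMAL_STEM_NODE)


def checker(h, w):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[::2, ::2] = 255
    return img


def mask_oracle_box(h, w, box, angle):
    """Bounding rectangle of a rasterized box mask after rotation."""
    from skimage.transform import rotate

    mask = np.zeros((h, w))
    mask[int(box.y_min) : int(box.y_max), int(box.x_min) : int(box.x_max)] = 1.0
    r = rotate(mask, angle, center=(w / 2 - 0.5, h / 2 - 0.5), order=0, preserve_range=True)
    ys, xs = np.nonzero(r > 0.5)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1


class TestRotate:
    def test_identity_at_zero(self):
        img = checker(60, 60)
        boxes = [ann(5, 10, 20, 30)]
        out_img, out_boxes = rotate_image_and_boxes(img, boxes, 0.0)
        assert np.array_equal(out_img, img)
        assert out_boxes == boxes

    def test_quarter_turn_corner_mapping(self):
        """90-degree rotation of box (10,20,40,60) on a 100x100 image."""
        img = checker(100, 100)
        _, boxes = rotate_image_and_boxes(img, [ann(10, 20, 40, 60)], 90.0)
        assert boxes[0].box.as_tuple() == pytest.approx((20, 60, 60, 90))

    @pytest.mark.parametrize("angle", [90.0, 33.0, 180.0, 247.5])
    def test_matches_rasterized_mask_oracle(self, angle):
        h = w = 120
        box = BoundingBox(30, 44, 72, 80)
        _, boxes = rotate_image_and_boxes(checker(h, w), [ann(*box.as_tuple())], angle)
        oracle = mask_oracle_box(h, w, box, angle)
        assert boxes[0].box.as_tuple() == pytest.approx(oracle, abs=1.5)

    def test_hull_growth_under_back_rotation(self):
        """Rotating by a then -a never shrinks a box (axis-aligned hulls)."""
        img = checker(100, 100)
        original = ann(30, 30, 55, 70)
        for angle in (17.0, 45.0, 90.0):
            _, once = rotate_image_and_boxes(img, [original], angle)
            _, back = rotate_image_and_boxes(img, once, -angle)
            assert back[0].box.area >= original.box.area - 1e-6
        _, once = rotate_image_and_boxes(img, [original], 90.0)
        _, back = rotate_image_and_boxes(img, once, -90.0)
        assert back[0].box.area == pytest.approx(original.box.area)


class TestRandomCrop:
    def test_whole_image_crop_keeps_boxes(self):
        img = checker(80, 80)
        boxes = [ann(10, 10, 30, 30), ann(50, 55, 70, 75)]
        cfg = AugmentationConfig(crop_size=80)
        out_img, out_boxes = random_crop(img, boxes, cfg, np.random.default_rng(0))
        assert out_img.shape == (80, 80, 3)
        assert out_boxes == boxes

    def test_box_outside_crop_dropped(self):
        img = checker(100, 100)
        cfg = AugmentationConfig(crop_size=40)
        rng = np.random.default_rng(3)
        # force origin (0, 0) by padding-free 100-40 range: draw until origin known
        out_img, out_boxes = random_crop(img[:40, :40], [ann(60, 60, 80, 80)], cfg, rng)
        assert out_boxes == []

    def test_visibility_threshold_boundary(self):
        """A box exactly half inside survives at 0.5 but not at 0.6; the
        visible fraction agrees with a pixel-mask counting oracle."""
        img = checker(40, 80)
        box = BoundingBox(30, 10, 50, 30)  # right half beyond x=40
        mask = np.zeros((40, 80), bool)
        mask[10:30, 30:50] = True
        oracle_fraction = mask[:, :40].sum() / mask.sum()
        assert oracle_fraction == pytest.approx(0.5)

        for min_vis, expect_kept in [(0.5, True), (0.6, False)]:
            cfg = AugmentationConfig(crop_size=40, min_box_visibility=min_vis)
            out_img, out_boxes = random_crop(
                img[:, :40], [AnnotationBox(box, Category.NORMAL_STEM_NODE)], cfg,
                np.random.default_rng(0),
            )
            assert bool(out_boxes) is expect_kept
        assert out_img.shape[:2] == (40, 40)

    def test_small_image_reflection_padded(self):
        img = checker(30, 30)
        cfg = AugmentationConfig(crop_size=50)
        out_img, _ = random_crop(img, [], cfg, np.random.default_rng(1))
        assert out_img.shape == (50, 50, 3)


@pytest.fixture(scope="module")
def specimen():
    return generate_specimen(
        TaxonLabel.HYEMALE,
        SyntheticParams(image_size=300, nodes_per_stem=(3, 5), stems_per_image=(1, 2)),
        seed=4,
    )


class TestAugment:

    def test_deterministic(self, specimen):
        cfg = AugmentationConfig(crop_size=200)
        a = augment(specimen, cfg, np.random.default_rng(8))
        b = augment(specimen, cfg, np.random.default_rng(8))
        assert np.array_equal(a.image, b.image)
        assert a.annotations == b.annotations

    def test_distinct_samples_under_different_states(self, specimen):
        cfg = AugmentationConfig(crop_size=200)
        rng = np.random.default_rng(0)
        outputs = {augment(specimen, cfg, rng).image.tobytes() for _ in range(20)}
        assert len(outputs) > 1

    def test_output_boxes_satisfy_invariants(self, specimen):
        cfg = AugmentationConfig(crop_size=200)
        rng = np.random.default_rng(2)
        for _ in range(25):
            out = augment(specimen, cfg, rng)
            assert out.image.shape[:2] == (200, 200)
            for a in out.annotations:
                assert 0 <= a.box.x_min < a.box.x_max <= 200
                assert 0 <= a.box.y_min < a.box.y_max <= 200

    def test_boxes_still_cover_node_pixels(self, specimen):
        """Augmented ground-truth boxes keep at least min_box_visibility of
        their node's pixel mask (mask transformed alongside the image)."""
        from skimage.transform import rotate as sk_rotate

        h, w = specimen.image.shape[:2]
        cfg = AugmentationConfig(crop_size=200, min_box_visibility=0.5)
        base_rng = np.random.default_rng(31)
        for trial in range(5):
            state = base_rng.integers(2**32)
            # replicate augment's internal draws to transform masks identically
            rng1 = np.random.default_rng(state)
            out = augment(specimen, cfg, rng1)

            rng2 = np.random.default_rng(state)
            angle = float(rng2.uniform(*cfg.angle_range))
            oy_ox_rng = rng2  # consumed by the crop below

            # build one mask per original node, rotate, crop with same origin
            masks = []
            for a in specimen.annotations:
                m = np.zeros((h, w))
                m[int(a.box.y_min) : int(a.box.y_max), int(a.box.x_min) : int(a.box.x_max)] = 1
                masks.append(
                    sk_rotate(m, angle, center=(w / 2 - 0.5, h / 2 - 0.5), order=0, preserve_range=True)
                )
            oy = int(oy_ox_rng.integers(0, h - cfg.crop_size + 1))
            ox = int(oy_ox_rng.integers(0, w - cfg.crop_size + 1))
            for a_out in out.annotations:
                x0, y0, x1, y1 = (int(round(v)) for v in a_out.box.as_tuple())
                covered = [
                    m[oy + y0 : oy + y1, ox + x0 : ox + x1].sum() / max(m.sum(), 1)
                    for m in masks
                    if m.sum() > 0
                ]
                assert max(covered) >= cfg.min_box_visibility * 0.8
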