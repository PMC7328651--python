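"""Detector training augmentation: random rotation + fixed-size crop.

Each training image is rotated by a random angle about its center and a
random ``crop_size`` x ``crop_size`` sub-image is cut from it; bounding
boxes are transformed consistently. Rotated boxes become the axis-aligned
hull of their four rotated corners (the standard convention for
axis-aligned detectors); boxes that keep less than ``min_box_visibility``
of their area inside the crop are dropped, the rest are clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .types import AnnotatedImage, AnnotationBox, BoundingBox, ValidationError


@dataclass(frozen=True)
class AugmentationConfig:
    crop_size: int = 500
    angle_range: tuple[float, float] = (0.0, 360.0)
    min_box_visibility: float = 0.5

    def __post_init__(self) -> None:
        if self.crop_size <= 0:
            raise ValidationError("crop_size must be positive")
        if not (0.0 < self.min_box_visibility <= 1.0):
            raise ValidationError("min_box_visibility must lie in (0, 1]")


def _rotate_corners(box: BoundingBox, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate the four corners of a box about ``center`` (image CCW)."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    # visual counter-clockwise rotation in image coordinates (y down)
    rot = np.array([[c, s], [-s, c]])
    corners = np.array(
        [
            [box.x_min, box.y_min],
            [box.x_max, box.y_min],
            [box.x_min, box.y_max],
            [box.x_max, box.y_max],
        ]
    )
    return (corners - center) @ rot.T + center


def rotate_image_and_boxes(
    image: np.ndarray,
    boxes: Sequence[AnnotationBox],
    angle: float,
    fill: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, list[AnnotationBox]]:
    """Rotate image and boxes counter-clockwise by ``angle`` degrees.

    The image rotates about its center with ``fill`` (default: the mean
    image color, which avoids dark wedges at the corners). Each output box
    is the axis-aligned bounding rectangle of the rotated input box's
    corners, clipped to the image; boxes rotated fully outside are dropped.
    """
    h, w = image.shape[:2]
    if fill is None:
        fill = image.reshape(-1, image.shape[-1]).mean(axis=0) if image.ndim == 3 else float(image.mean())
    if angle % 360 == 0:
        return image.copy(), list(boxes)

    rotated = np.empty_like(image)
    if image.ndim == 3:
        for ch in range(image.shape[2]):
            rotated[..., ch] = _sk_rotate(
                image[..., ch].astype(np.float64),
                angle,
                resize=False,
                center=(w / 2 - 0.5, h / 2 - 0.5),
                cval=float(np.asarray(fill).ravel()[ch]),
                preserve_range=True,
                order=1,
            ).astype(image.dtype)
    else:
        rotated = _sk_rotate(
            image.astype(np.float64), angle, resize=False,
            center=(w / 2 - 0.5, h / 2 - 0.5), cval=float(fill),
            preserve_range=True, order=1,
        ).astype(image.dtype)

    center = (w / 2.0, h / 2.0)
    out_boxes: list[AnnotationBox] = []
    for ann in boxes:
        pts = _rotate_corners(ann.box, angle, center)
        hull = BoundingBox(
            max(0.0, float(pts[:, 0].min())),
            max(0.0, float(pts[:, 1].min())),
            max(1e-6, float(pts[:, 0].max())),
            max(1e-6, float(pts[:, 1].max())),
        )
        clipped = hull.clip(w, h)
        if clipped is not None:
            out_boxes.append(AnnotationBox(box=clipped, category=ann.category))
    return rotated, out_boxes


def random_crop(
    image: np.ndarray,
    boxes: Sequence[AnnotationBox],
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[AnnotationBox]]:
    """Cut a random ``crop_size`` square; translate, filter, and clip boxes.

    Images smaller than the crop are reflection-padded first. A box is kept
    iff the fraction of its area visible inside the crop window is at least
    ``min_box_visibility``.
    """
    h, w = image.shape[:2]
    cs = config.crop_size
    pad_y = max(0, cs - h)
    pad_x = max(0, cs - w)
    if pad_y or pad_x:
        pad = [(0, pad_y), (0, pad_x)] + [(0, 0)] * (image.ndim - 2)
        image = np.pad(image, pad, mode="reflect")
        h, w = image.shape[:2]

    oy = int(rng.integers(0, h - cs + 1))
    ox = int(rng.integers(0, w - cs + 1))
    crop = image[oy : oy + cs, ox : ox + cs].copy()

    out: list[AnnotationBox] = []
    for ann in boxes:
        b = ann.box
        ix0, iy0 = max(b.x_min, ox), max(b.y_min, oy)
        ix1, iy1 = min(b.x_max, ox + cs), min(b.y_max, oy + cs)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        visible = (ix1 - ix0) * (iy1 - iy0) / b.area
        if visible < config.min_box_visibility:
            continue
        out.append(
            AnnotationBox(
                box=BoundingBox(ix0 - ox, iy0 - oy, ix1 - ox, iy1 - oy),
                category=ann.category,
            )
        )
    return crop, out


def augment(
    annotated: AnnotatedImage, config: AugmentationConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Rotate by a random angle, then crop a random square; seeded."""
    if annotated.image is None:
        raise ValidationError("augment requires pixel data on the AnnotatedImage")
    angle = float(rng.uniform(*config.angle_range))
    img, boxes = rotate_image_and_boxes(annotated.image, annotated.annotations, angle)
    img, boxes = random_crop(img, boxes, config, rng)
    return annotated.with_(image=img, annotations=boxes)
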