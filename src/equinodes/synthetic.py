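"""Synthetic pressed-specimen images with ground-truth annotations.

The generator emulates the morphological contrast the pipeline exploits:

* hyemale-type (H) nodes — leaf sheaths prominently cross-banded, with a
  dark horizontal stripe near the base, a tan/ashy-white region above it,
  and another dark band at the rim;
* laevigatum-type (L) nodes — sheaths mostly green with a narrow black rim;
* hybrid specimens — H-type sheaths predominate toward the stem base and
  L-type sheaths toward the apex, with a monotone probability gradient in
  between.

Images are drawn on a paper-like background with slightly curved green
stems; every rendered node gets a tight ground-truth box of category
``normal_stem_node``. All randomness flows from a single seeded generator
per call, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import annotation_io
from .types import (
    AnnotatedImage,
    AnnotationBox,
    BoundingBox,
    Category,
    NodeType,
    TaxonLabel,
    ValidationError,
)

PAPER_COLOR = np.array([233.0, 227.0, 211.0])
STEM_COLOR = np.array([112.0, 131.0, 76.0])
H_DARK = np.array([52.0, 46.0, 40.0])
H_LIGHT = np.array([206.0, 196.0, 168.0])
L_GREEN = np.array([104.0, 152.0, 70.0])
L_RIM = np.array([34.0, 32.0, 28.0])
STROBILUS_COLOR = np.array([70.0, 55.0, 35.0])

TAXON_ORDER = (TaxonLabel.HYEMALE, TaxonLabel.LAEVIGATUM, TaxonLabel.FERRISSII)


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the specimen generator.

    ``hybrid_gradient = (p_base, p_apex)`` gives the probability that a
    hybrid node is H-type at the stem base / apex; H must predominate
    basally (``p_base >= p_apex``). ``node_size`` is the nominal sheath
    height in pixels and must not fall below the detector's smallest-object
    pitch of 30 px.
    """

    image_size: int = 700
    stems_per_image: tuple[int, int] = (1, 3)
    nodes_per_stem: tuple[int, int] = (6, 12)
    node_size: int = 36
    stem_curvature: tuple[float, float] = (-0.15, 0.15)  # radians of lateral lean
    hybrid_gradient: tuple[float, float] = (0.9, 0.1)
    background_noise: float = 4.0
    gradient_form: str = "linear"  # or "logistic"
    render_strobili: bool = False

    def __post_init__(self) -> None:
        p_base, p_apex = self.hybrid_gradient
        if not (0.0 <= p_apex <= 1.0 and 0.0 <= p_base <= 1.0):
            raise ValidationError("hybrid_gradient probabilities must lie in [0, 1]")
        if p_base < p_apex:
            raise ValidationError("hybrid gradient requires p_base >= p_apex (H predominates basally)")
        if self.node_size < 30:
            raise ValidationError("node_size must be >= 30 px (detector grid pitch)")
        if self.gradient_form not in ("linear", "logistic"):
            raise ValidationError("gradient_form must be 'linear' or 'logistic'")
        if self.stems_per_image[0] < 1 or self.nodes_per_stem[0] < 1:
            raise ValidationError("stems_per_image and nodes_per_stem must start at >= 1")


def render_node(node_type: NodeType, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one leaf-sheath patch of ``size`` x ``size`` pixels (uint8 RGB).

    H patches carry a dark/light/dark horizontal band triplet; L patches a
    green field with a single thin dark rim. Band widths and hue are
    jittered per patch from ``rng``.
    """
    if size < 8:
        raise ValidationError(f"node patch size must be >= 8 px, got {size}")
    if node_type not in (NodeType.H, NodeType.L):
        raise ValidationError(
            "only H and L sheaths have a rendered appearance; hybrid nodes are drawn as H or L"
        )
    patch = np.empty((size, size, 3), dtype=np.float64)
    hue_shift = rng.normal(0.0, 6.0, size=3)
    if node_type == NodeType.H:
        # fractions of the patch height, top to bottom: light margin, dark
        # rim band, tan/ashy region, dark basal stripe, light margin
        jitter = rng.uniform(0.8, 1.2, size=3)
        f_rim, f_light, f_base = 0.18 * jitter[0], 0.40 * jitter[1], 0.20 * jitter[2]
        margin = max(1, int(round(size * (1.0 - f_rim - f_light - f_base) / 2)))
        r0 = margin
        r1 = r0 + max(2, int(round(size * f_rim)))
        r2 = r1 + max(2, int(round(size * f_light)))
        r3 = min(size - margin, r2 + max(2, int(round(size * f_base))))
        patch[:] = H_LIGHT * 0.92 + hue_shift  # pale sheath margins
        patch[r0:r1] = H_DARK + hue_shift
        patch[r1:r2] = H_LIGHT + hue_shift
        patch[r2:r3] = H_DARK * 1.1 + hue_shift
    else:
        rim_top = max(1, int(round(size * rng.uniform(0.06, 0.12))))
        rim_h = max(2, int(round(size * rng.uniform(0.08, 0.14))))
        patch[:] = L_GREEN + hue_shift
        patch[rim_top : rim_top + rim_h] = L_RIM + hue_shift * 0.3
    patch += rng.normal(0.0, 3.0, size=patch.shape)
    return np.clip(patch, 0, 255).astype(np.uint8)


def hybrid_node_type(
    relative_position: float, params: SyntheticParams, rng: np.random.Generator
) -> NodeType:
    """Draw the type of a hybrid node at a relative stem position.

    ``relative_position`` runs from 0 (base) to 1 (apex). The probability
    of an H node interpolates between ``p_base`` and ``p_apex`` — linearly
    by default, or with a logistic ramp when ``gradient_form='logistic'``.
    """
    if not (0.0 <= relative_position <= 1.0):
        raise ValidationError(f"relative_position must lie in [0, 1], got {relative_position}")
    p_base, p_apex = params.hybrid_gradient
    if params.gradient_form == "linear":
        p = p_base + (p_apex - p_base) * relative_position
    else:
        # logistic ramp from ~p_base at 0 to ~p_apex at 1, steepness 8
        w = 1.0 / (1.0 + np.exp(-8.0 * (relative_position - 0.5)))
        p = p_base + (p_apex - p_base) * w
    return NodeType.H if rng.random() < p else NodeType.L


def generate_specimen(
    taxon: TaxonLabel, params: SyntheticParams, seed: int
) -> AnnotatedImage:
    """Generate one synthetic specimen image with ground-truth boxes.

    Node types follow the taxon: hyemale -> all H, laevigatum -> all L,
    ferrissii -> :func:`hybrid_node_type` of the relative position along
    the stem (base at the bottom of the image). Deterministic given
    ``(taxon, params, seed)``.
    """
    size = params.image_size
    if size < 3 * params.node_size:
        raise ValidationError(
            f"image_size {size} too small to fit one stem of node_size {params.node_size}"
        )
    rng = np.random.default_rng(seed)

    canvas = np.empty((size, size, 3), dtype=np.float64)
    canvas[:] = PAPER_COLOR
    # gentle lighting gradient plus pixel noise, as on scanned sheets
    grad = np.linspace(-4.0, 4.0, size)[:, None, None]
    canvas += grad
    if params.background_noise > 0:
        canvas += rng.normal(0.0, params.background_noise, size=canvas.shape)

    n_stems = int(rng.integers(params.stems_per_image[0], params.stems_per_image[1] + 1))
    margin = int(params.node_size * 0.8)
    slot_w = size / n_stems
    annotations: list[AnnotationBox] = []

    for s in range(n_stems):
        x0 = slot_w * s + rng.uniform(0.35, 0.65) * slot_w
        lean = rng.uniform(*params.stem_curvature)
        bow = rng.uniform(-0.04, 0.04) * size
        y_base, y_apex = size - margin, margin
        ys = np.arange(y_apex, y_base)[::-1]  # bottom (base) to top (apex)
        t = (y_base - ys) / (y_base - y_apex)
        xs = x0 + np.tan(lean) * (y_base - ys) + bow * np.sin(np.pi * t)
        xs = np.clip(xs, margin, size - margin - 1)
        half_w = max(2, params.node_size // 12)
        xi = xs.astype(int)
        for y, x in zip(ys, xi):
            canvas[y, max(0, x - half_w) : min(size, x + half_w + 1)] = STEM_COLOR

        # node placement: regular intervals, at least 1.5 node heights apart
        stem_len = y_base - y_apex
        n_max = max(1, int(stem_len / (1.5 * params.node_size)))
        n_nodes = int(rng.integers(params.nodes_per_stem[0], params.nodes_per_stem[1] + 1))
        n_nodes = min(n_nodes, n_max)
        for i in range(n_nodes):
            rel = (i + 0.5) / n_nodes  # 0 = base, 1 = apex
            if taxon == TaxonLabel.HYEMALE:
                ntype = NodeType.H
            elif taxon == TaxonLabel.LAEVIGATUM:
                ntype = NodeType.L
            else:
                ntype = hybrid_node_type(rel, params, rng)
            psize = int(round(params.node_size * rng.uniform(0.95, 1.25)))
            patch = render_node(ntype, psize, rng)
            cy = int(round(y_base - rel * stem_len))
            cx = int(round(np.interp(cy, ys[::-1], xs[::-1])))
            cx = int(np.clip(cx, psize // 2, size - psize // 2 - 1))
            top = int(np.clip(cy - psize // 2, 0, size - psize))
            left = cx - psize // 2
            canvas[top : top + psize, left : left + psize] = patch
            annotations.append(
                AnnotationBox(
                    box=BoundingBox(left, top, left + psize, top + psize),
                    category=Category.NORMAL_STEM_NODE,
                )
            )
        if params.render_strobili:
            sx, sy = int(xs[-1]), y_apex
            r = max(4, params.node_size // 4)
            yy, xx = np.ogrid[max(0, sy - 2 * r) : sy + r, max(0, sx - r) : sx + r]
            mask = ((xx - sx) / r) ** 2 + ((yy - (sy - r)) / (1.6 * r)) ** 2 <= 1.0
            canvas[max(0, sy - 2 * r) : sy + r, max(0, sx - r) : sx + r][mask] = STROBILUS_COLOR
            annotations.append(
                AnnotationBox(
                    box=BoundingBox(
                        max(0, sx - r), max(0, sy - 2 * r), min(size, sx + r), min(size, sy + r)
                    ),
                    category=Category.STROBILUS,
                )
            )

    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return AnnotatedImage(
        image_id=f"{taxon.value}_{seed}", annotations=annotations, image=image, taxon=taxon
    )


def generate_dataset(
    n_per_taxon: int,
    params: SyntheticParams = SyntheticParams(),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Generate a balanced dataset of ``3 * n_per_taxon`` specimens.

    Returns the images and a manifest frame (image_id, taxon). When
    ``out_dir`` is given, writes PNGs, a VIA v2 project JSON
    (``annotations.json``), and ``manifest.csv``.
    """
    if n_per_taxon < 1:
        raise ValidationError("n_per_taxon must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(3 * n_per_taxon) % (2**31)
    images: list[AnnotatedImage] = []
    rows = []
    k = 0
    for taxon in TAXON_ORDER:
        for i in range(n_per_taxon):
            img = generate_specimen(taxon, params, int(child_seeds[k]))
            img = img.with_(image_id=f"{taxon.value}_{i:03d}.png")
            images.append(img)
            rows.append({"image_id": img.image_id, "taxon": taxon.value})
            k += 1
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img in images:
            Image.fromarray(img.image).save(out_dir / img.image_id)
        annotation_io.write_via(images, out_dir / "annotations.json")
        annotation_io.write_manifest(manifest, out_dir / "manifest.csv")
    return images, manifest
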