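"""Anchor-grid single-stage node detector.

The detector superimposes a regular grid of sample points on the image
(pitch 30 px, the size of the smallest node it should find) and, at each
point, scores 36 candidate rectangles (6 sizes x 6 aspect ratios). A single
model jointly classifies every anchor into {background} ∪ {H, L[, F]} and
regresses center/size offsets; overlapping outputs are removed by greedy
non-maximum suppression.

The scoring model is deliberately compact so that training runs on one CPU
in minutes: each anchor is described by integral-image pooled color
features (a 3x3 cell grid plus a 6-band vertical profile, which captures
the dark/light/dark banding of hyemale-type sheaths versus the green field
of laevigatum-type sheaths), and a one-hidden-layer network maps features
to class logits and box offsets. Training follows the usual single-shot
recipe: mini-batch gradient descent on a joint softmax cross-entropy +
smooth-L1 loss with 3:1 hard-negative mining, random rotation + 500x500
crop augmentation, and validation-based early stopping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augmentation import AugmentationConfig, augment
from .types import (
    AnnotatedImage,
    BoundingBox,
    Category,
    Detection,
    NodeType,
    ValidationError,
)

logger = logging.getLogger(__name__)

NODE_CATEGORIES = (Category.NORMAL_STEM_NODE, Category.INJURED_STEM_NODE)


@dataclass(frozen=True)
class AnchorSpec:
    """Anchor layout: grid pitch and per-point box shapes.

    Defaults: pitch 30 px; six sizes in geometric progression 30–120 px;
    six width/height ratios spanning squat to tall rectangles, giving
    36 anchors per grid point.
    """

    pitch: int = 30
    sizes: tuple[float, ...] = (30.0, 40.0, 52.0, 69.0, 91.0, 120.0)
    aspect_ratios: tuple[float, ...] = (1 / 3, 1 / 2, 2 / 3, 1.0, 3 / 2, 2.0)

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValidationError("pitch must be positive")
        if not self.sizes or not self.aspect_ratios:
            raise ValidationError("sizes and aspect_ratios must be non-empty")

    @property
    def anchors_per_point(self) -> int:
        return len(self.sizes) * len(self.aspect_ratios)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 8
    learning_rate: float = 0.001
    max_iterations: int = 2000
    patience: int = 5
    eval_every: int = 50
    crops_per_image: int = 4
    hidden_units: int = 64
    neg_pos_ratio: int = 3
    neg_store: int = 512
    loc_weight: float = 2.0

    def __post_init__(self) -> None:
        for name in ("batch_size", "learning_rate", "max_iterations", "patience"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def build_anchor_grid(
    image_size: int | tuple[int, int], spec: AnchorSpec = AnchorSpec()
) -> np.ndarray:
    """All anchors for an image, as an (N, 4) array of (x0, y0, x1, y1).

    Grid points sit at ``(i + 0.5) * pitch`` in each dimension; each point
    carries one anchor per (size, ratio) pair, centered on the point with
    width ``size * sqrt(ratio)`` and height ``size / sqrt(ratio)``, clipped
    to the image bounds. Ordering is grid-major, then sizes, then ratios.
    """
    if isinstance(image_size, (int, np.integer)):
        h = w = int(image_size)
    else:
        h, w = int(image_size[0]), int(image_size[1])
    if min(h, w) < spec.pitch:
        raise ValidationError(f"image {h}x{w} smaller than grid pitch {spec.pitch}")
    ny, nx = h // spec.pitch, w // spec.pitch
    cy = (np.arange(ny) + 0.5) * spec.pitch
    cx = (np.arange(nx) + 0.5) * spec.pitch
    sizes = np.asarray(spec.sizes, dtype=np.float64)
    ratios = np.asarray(spec.aspect_ratios, dtype=np.float64)
    ws = (sizes[:, None] * np.sqrt(ratios)[None, :]).ravel()  # per-point widths
    hs = (sizes[:, None] / np.sqrt(ratios)[None, :]).ravel()

    gy, gx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (P, 2)
    boxes = np.empty((centers.shape[0] * ws.size, 4), dtype=np.float64)
    for i, (aw, ah) in enumerate(zip(ws, hs)):
        boxes[i :: ws.size, 0] = centers[:, 0] - aw / 2
        boxes[i :: ws.size, 1] = centers[:, 1] - ah / 2
        boxes[i :: ws.size, 2] = centers[:, 0] + aw / 2
        boxes[i :: ws.size, 3] = centers[:, 1] + ah / 2
    # interleave so ordering is grid-major: reshape to (P, A, 4)
    boxes = boxes.reshape(ws.size, -1, 4, order="F").transpose(1, 0, 2).reshape(-1, 4)
    boxes[:, 0] = np.clip(boxes[:, 0], 0, w)
    boxes[:, 1] = np.clip(boxes[:, 1], 0, h)
    boxes[:, 2] = np.clip(boxes[:, 2], 0, w)
    boxes[:, 3] = np.clip(boxes[:, 3], 0, h)
    return boxes


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) box arrays."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0,
        None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0,
        None,
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _nms_key(d: Detection) -> tuple:
    return (-d.score, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)


def suppress_overlaps(
    detections: Sequence[Detection], overlap_threshold: float = 0.5
) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited in descending score (ties: smaller
    ``(x_min, y_min)`` first); one is kept iff its IoU with every
    already-kept detection is ``<= overlap_threshold``. The result is a
    function of the set of inputs only, not of their order.
    """
    kept: list[Detection] = []
    kept_boxes: list[np.ndarray] = []
    for det in sorted(detections, key=_nms_key):
        b = np.array(det.box.as_tuple())
        if kept_boxes:
            ious = iou_matrix(b[None, :], np.stack(kept_boxes))[0]
            if (ious > overlap_threshold).any():
                continue
        kept.append(det)
        kept_boxes.append(b)
    return kept


def encode_offsets(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """SSD-style center/size deltas of ground truth relative to anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack(
        [(gcx - acx) / aw, (gcy - acy) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def decode_offsets(anchors: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = acx + offsets[:, 0] * aw
    cy = acy + offsets[:, 1] * ah
    w = aw * np.exp(np.clip(offsets[:, 2], -4, 4))
    h = ah * np.exp(np.clip(offsets[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def assign_training_targets(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    match_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor class targets and box-regression offsets.

    Every anchor with IoU >= ``match_threshold`` against some ground-truth
    box is positive (assigned to its best-IoU box); additionally each
    ground-truth box claims its single best-IoU anchor, so no annotation
    goes unmatched. All other anchors are background (label 0). Positive
    labels are ``gt_labels`` values (1-based type indices).
    """
    n = anchors.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    offsets = np.zeros((n, 4), dtype=np.float64)
    if gt_boxes.size == 0:
        return labels, offsets
    gt_boxes = np.atleast_2d(gt_boxes)
    m = iou_matrix(anchors, gt_boxes)  # (N, M)
    best_gt = m.argmax(axis=1)
    best_iou = m[np.arange(n), best_gt]
    positive = best_iou >= match_threshold
    # force-match each ground truth to its best anchor
    forced = m.argmax(axis=0)
    positive[forced] = True
    best_gt[forced] = np.arange(gt_boxes.shape[0])

    idx = np.nonzero(positive)[0]
    labels[idx] = gt_labels[best_gt[idx]]
    offsets[idx] = encode_offsets(anchors[idx], gt_boxes[best_gt[idx]])
    return labels, offsets


# ---------------------------------------------------------------------------
# features


def _integral(image: np.ndarray) -> np.ndarray:
    h, w, c = image.shape
    ii = np.zeros((h + 1, w + 1, c), dtype=np.float64)
    ii[1:, 1:] = image.astype(np.float64).cumsum(axis=0).cumsum(axis=1)
    return ii


def _box_sums(ii: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    return ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]


N_CELL = 3  # 3x3 color grid
N_BANDS = 6  # vertical intensity profile bands
FEATURE_DIM = N_CELL * N_CELL * 3 + N_BANDS * 3 + 2


def anchor_features(image: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Pooled color features for each box: 3x3 RGB cell means, a 6-band
    top-to-bottom RGB profile, and log box dimensions. O(1) per cell via
    integral images."""
    h, w = image.shape[:2]
    ii = _integral(image / 255.0)
    boxes = np.atleast_2d(boxes)
    n = boxes.shape[0]

    def grid_means(nx: int, ny: int) -> np.ndarray:
        xs = boxes[:, 0:1] + (boxes[:, 2:3] - boxes[:, 0:1]) * np.linspace(0, 1, nx + 1)
        ys = boxes[:, 1:2] + (boxes[:, 3:4] - boxes[:, 1:2]) * np.linspace(0, 1, ny + 1)
        xi = np.clip(np.round(xs).astype(np.int64), 0, w)
        yi = np.clip(np.round(ys).astype(np.int64), 0, h)
        # guarantee at least one pixel per cell
        for k in range(1, xi.shape[1]):
            xi[:, k] = np.maximum(xi[:, k], np.minimum(xi[:, k - 1] + 1, w))
        for k in range(1, yi.shape[1]):
            yi[:, k] = np.maximum(yi[:, k], np.minimum(yi[:, k - 1] + 1, h))
        out = np.empty((n, ny, nx, 3))
        for r in range(ny):
            for c in range(nx):
                x0, x1 = xi[:, c], xi[:, c + 1]
                y0, y1 = yi[:, r], yi[:, r + 1]
                area = np.maximum((x1 - x0) * (y1 - y0), 1)
                out[:, r, c] = _box_sums(ii, x0, y0, x1, y1) / area[:, None]
        return out.reshape(n, -1)

    cells = grid_means(N_CELL, N_CELL)
    profile = grid_means(1, N_BANDS)
    dims = np.stack(
        [
            np.log(np.maximum(boxes[:, 2] - boxes[:, 0], 1.0) / 30.0),
            np.log(np.maximum(boxes[:, 3] - boxes[:, 1], 1.0) / 30.0),
        ],
        axis=1,
    )
    return np.concatenate([cells, profile, dims], axis=1)


# ---------------------------------------------------------------------------
# model


@dataclass
class DetectorModel:
    """A trained anchor-grid detector (or an untrained shell before fit)."""

    anchor_spec: AnchorSpec = field(default_factory=AnchorSpec)
    type_set: tuple[NodeType, ...] = (NodeType.H, NodeType.L)
    params: Optional[dict] = None  # weight arrays
    feat_mean: Optional[np.ndarray] = None
    feat_scale: Optional[np.ndarray] = None

    @property
    def is_trained(self) -> bool:
        return self.params is not None

    @property
    def n_classes(self) -> int:
        return 1 + len(self.type_set)

    def forward(self, feats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (class probabilities, offsets, hidden activations)."""
        if not self.is_trained:
            raise ValidationError("detector model has not been trained")
        x = (feats - self.feat_mean) / self.feat_scale
        p = self.params
        h = np.maximum(x @ p["W1"] + p["b1"], 0.0)
        logits = h @ p["Wc"] + p["bc"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        offsets = h @ p["Wr"] + p["br"]
        return probs, offsets, h

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        arrays["feat_mean"] = self.feat_mean
        arrays["feat_scale"] = self.feat_scale
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "anchor_spec": {
                "pitch": self.anchor_spec.pitch,
                "sizes": list(self.anchor_spec.sizes),
                "aspect_ratios": list(self.anchor_spec.aspect_ratios),
            },
            "type_set": [t.value for t in self.type_set],
            "weights_sha256": hashlib.sha256(
                path.with_suffix(".npz").read_bytes()
            ).hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        params = {k: data[k] for k in data.files if k not in ("feat_mean", "feat_scale")}
        spec = AnchorSpec(
            pitch=sidecar["anchor_spec"]["pitch"],
            sizes=tuple(sidecar["anchor_spec"]["sizes"]),
            aspect_ratios=tuple(sidecar["anchor_spec"]["aspect_ratios"]),
        )
        return cls(
            anchor_spec=spec,
            type_set=tuple(NodeType(t) for t in sidecar["type_set"]),
            params=params,
            feat_mean=data["feat_mean"],
            feat_scale=data["feat_scale"],
        )


def _init_params(rng: np.random.Generator, d_in: int, hidden: int, n_classes: int) -> dict:
    return {
        "W1": rng.normal(0, np.sqrt(2.0 / d_in), (d_in, hidden)),
        "b1": np.zeros(hidden),
        "Wc": rng.normal(0, np.sqrt(1.0 / hidden), (hidden, n_classes)),
        "bc": np.zeros(n_classes),
        "Wr": rng.normal(0, np.sqrt(1.0 / hidden), (hidden, 4)),
        "br": np.zeros(4),
    }


def _node_targets(img: AnnotatedImage, type_set: tuple[NodeType, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth node boxes and proxy type labels (1-based) for an image.

    Every node in an image is labeled by the image's taxon: H in hyemale
    images, L in laevigatum images, F in ferrissii images (three-type mode).
    """
    if img.taxon is None:
        raise ValidationError(f"{img.image_id}: taxon label required for proxy node typing")
    ntype = NodeType.for_taxon(img.taxon)
    if ntype not in type_set:
        raise ValidationError(
            f"{img.image_id}: taxon {img.taxon.value} outside detector type set "
            f"{[t.value for t in type_set]}"
        )
    label = type_set.index(ntype) + 1
    boxes = np.array(
        [a.box.as_tuple() for a in img.annotations if a.category in NODE_CATEGORIES]
    ).reshape(-1, 4)
    return boxes, np.full(boxes.shape[0], label, dtype=np.int64)


def _prepare_samples(
    images: Sequence[AnnotatedImage],
    type_set: tuple[NodeType, ...],
    aug_config: AugmentationConfig,
    spec: AnchorSpec,
    config: TrainingConfig,
    rng: np.random.Generator,
    crops_per_image: int,
) -> list[dict]:
    """Augmented crops with precomputed anchor features and targets."""
    anchors = build_anchor_grid(aug_config.crop_size, spec)
    samples = []
    for img in images:
        for _ in range(crops_per_image):
            crop = augment(img, aug_config, rng)
            boxes, type_labels = _node_targets(crop, type_set)
            labels, offsets = assign_training_targets(anchors, boxes, type_labels)
            pos = np.nonzero(labels > 0)[0]
            if boxes.size:
                best_iou = iou_matrix(anchors, boxes).max(axis=1)
            else:
                best_iou = np.zeros(anchors.shape[0])
            # anchors loosely overlapping a node are kept as explicit hard
            # negatives; a narrow band just under the match threshold is
            # ignored (ambiguous either way)
            near = np.nonzero((labels == 0) & (best_iou >= 0.15) & (best_iou < 0.4))[0]
            far = np.nonzero((labels == 0) & (best_iou < 0.15))[0]
            if near.size > config.neg_store // 2:
                near = rng.choice(near, size=config.neg_store // 2, replace=False)
            n_far = max(0, config.neg_store - near.size)
            if far.size > n_far:
                far = rng.choice(far, size=n_far, replace=False)
            sel = np.concatenate([pos, near, far])
            feats = anchor_features(crop.image, anchors[sel])
            samples.append(
                {
                    "feats": feats.astype(np.float32),
                    "labels": labels[sel],
                    "offsets": offsets[sel].astype(np.float32),
                    "n_pos": pos.size,
                }
            )
    return samples


def _smooth_l1_grad(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    absd = np.abs(diff)
    loss = np.where(absd < 1.0, 0.5 * diff**2, absd - 0.5)
    grad = np.clip(diff, -1.0, 1.0)
    return loss, grad


def train_detector(
    train: Sequence[AnnotatedImage],
    val: Sequence[AnnotatedImage],
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    anchor_spec: AnchorSpec = AnchorSpec(),
    type_set: tuple[NodeType, ...] = (NodeType.H, NodeType.L),
    aug_config: AugmentationConfig = AugmentationConfig(),
) -> tuple[DetectorModel, dict]:
    """Train the detector with mini-batch gradient descent.

    Each iteration draws ``batch_size`` augmented crops and minimizes the
    joint loss (softmax cross-entropy over {background} ∪ type_set, plus
    smooth-L1 offset regression on positive anchors) with hard-negative
    mining at ``neg_pos_ratio`` negatives per positive. A validation error
    rate is computed every ``eval_every`` iterations; training returns the
    best-validation checkpoint, stopping early once the error has failed
    to improve ``patience`` consecutive evaluations.

    Returns ``(model, history)`` where history holds the loss trajectory
    and validation errors.
    """
    if not train:
        raise ValidationError("training set is empty")
    if not val:
        raise ValidationError("validation set is empty")
    rng = np.random.default_rng(seed)

    logger.info("preparing %d training images (%d crops each)", len(train), config.crops_per_image)
    tr_samples = _prepare_samples(train, type_set, aug_config, anchor_spec, config, rng, config.crops_per_image)
    va_samples = _prepare_samples(val, type_set, aug_config, anchor_spec, config, rng, max(1, config.crops_per_image // 2))

    all_feats = np.concatenate([s["feats"] for s in tr_samples])
    feat_mean = all_feats.mean(axis=0)
    feat_scale = all_feats.std(axis=0) + 1e-6

    n_classes = 1 + len(type_set)
    params = _init_params(rng, FEATURE_DIM, config.hidden_units, n_classes)
    model = DetectorModel(anchor_spec, type_set, params, feat_mean, feat_scale)

    # Adam state
    m_t = {k: np.zeros_like(v) for k, v in params.items()}
    v_t = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def val_error() -> float:
        wrong = total = 0
        for s in va_samples:
            probs, _, _ = model.forward(s["feats"])
            pred = probs.argmax(axis=1)
            # balance: all positives + an equal negative share
            pos = s["labels"] > 0
            wrong += int((pred[pos] != s["labels"][pos]).sum())
            total += int(pos.sum())
            neg = ~pos
            wrong += int((pred[neg] != 0).sum()) * max(1, int(pos.sum())) // max(1, int(neg.sum()))
            total += max(1, int(pos.sum()))
        return wrong / max(1, total)

    history = {"loss": [], "val_error": [], "stopped_at": None}
    best = {"error": np.inf, "params": {k: v.copy() for k, v in params.items()}}
    bad_evals = 0

    for it in range(1, config.max_iterations + 1):
        batch_ids = rng.integers(0, len(tr_samples), size=config.batch_size)
        feats, labels, offs = [], [], []
        for i in batch_ids:
            s = tr_samples[i]
            pos = np.nonzero(s["labels"] > 0)[0]
            neg = np.nonzero(s["labels"] == 0)[0]
            if pos.size and neg.size:
                probs, _, _ = model.forward(s["feats"][neg])
                hard = np.argsort(-(1.0 - probs[:, 0]))[: config.neg_pos_ratio * pos.size]
                neg = neg[hard]
            keep = np.concatenate([pos, neg])
            feats.append(s["feats"][keep])
            labels.append(s["labels"][keep])
            offs.append(s["offsets"][keep])
        X = np.concatenate(feats)
        y = np.concatenate(labels)
        t_off = np.concatenate(offs)
        if X.shape[0] == 0:
            continue

        probs, pred_off, hidden = model.forward(X)
        n = X.shape[0]
        ce = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
        pos_mask = y > 0
        n_pos = max(1, int(pos_mask.sum()))

        d_logits = probs.copy()
        d_logits[np.arange(n), y] -= 1.0
        d_logits /= n_pos

        d_off = np.zeros_like(pred_off)
        loc_loss = 0.0
        if pos_mask.any():
            diff = pred_off[pos_mask] - t_off[pos_mask]
            l, g = _smooth_l1_grad(diff)
            loc_loss = float(l.sum()) / n_pos
            d_off[pos_mask] = config.loc_weight * g / n_pos

        loss = float(ce.sum()) / n_pos + config.loc_weight * loc_loss
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss}; "
                "inspect learning_rate and feature scaling"
            )
        history["loss"].append(loss)

        x_std = (X - feat_mean) / feat_scale
        grads = {}
        grads["Wc"] = hidden.T @ d_logits
        grads["bc"] = d_logits.sum(axis=0)
        grads["Wr"] = hidden.T @ d_off
        grads["br"] = d_off.sum(axis=0)
        d_hidden = d_logits @ params["Wc"].T + d_off @ params["Wr"].T
        d_hidden[hidden <= 0] = 0.0
        grads["W1"] = x_std.T @ d_hidden
        grads["b1"] = d_hidden.sum(axis=0)

        step += 1
        for k in params:
            m_t[k] = beta1 * m_t[k] + (1 - beta1) * grads[k]
            v_t[k] = beta2 * v_t[k] + (1 - beta2) * grads[k] ** 2
            mhat = m_t[k] / (1 - beta1**step)
            vhat = v_t[k] / (1 - beta2**step)
            params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        if it % config.eval_every == 0 or it == config.max_iterations:
            err = val_error()
            history["val_error"].append((it, err))
            if err < best["error"] - 1e-9:
                best = {"error": err, "params": {k: v.copy() for k, v in params.items()}}
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= config.patience:
                    history["stopped_at"] = it
                    logger.info("early stop at iteration %d (val error %.4f)", it, best["error"])
                    break

    model.params = best["params"]
    history["best_val_error"] = best["error"]
    return model, history


def detect(
    model: DetectorModel,
    image: np.ndarray,
    score_threshold: float = 0.3,
    overlap_threshold: float = 0.3,
) -> list[Detection]:
    """Run the detector on one whole image.

    Every anchor is scored; the per-anchor type is the argmax over the type
    classes and its score the corresponding softmax probability. Anchors
    below ``score_threshold`` are dropped, offsets are decoded into refined
    boxes (clipped to the image), and greedy NMS removes overlaps.
    """
    if not model.is_trained:
        raise ValidationError("detect requires a trained model")
    h, w = image.shape[:2]
    anchors = build_anchor_grid((h, w), model.anchor_spec)
    feats = anchor_features(image, anchors)
    probs, offsets, _ = model.forward(feats)

    type_probs = probs[:, 1:]
    type_idx = type_probs.argmax(axis=1)
    scores = type_probs[np.arange(len(anchors)), type_idx]
    keep = scores >= score_threshold
    if not keep.any():
        return []
    boxes = decode_offsets(anchors[keep], offsets[keep])
    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, w)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, h)
    detections = []
    for b, ti, sc in zip(boxes, type_idx[keep], scores[keep]):
        if b[2] - b[0] < 1 or b[3] - b[1] < 1:
            continue
        detections.append(
            Detection(
                box=BoundingBox(*map(float, b)),
                node_type=model.type_set[int(ti)],
                score=float(sc),
            )
        )
    return suppress_overlaps(detections, overlap_threshold)


def detections_to_rows(image_id: str, detections: Sequence[Detection]) -> list[dict]:
    """Flatten detections for CSV export."""
    return [
        {
            "image_id": image_id,
            "x_min": d.box.x_min,
            "y_min": d.box.y_min,
            "x_max": d.box.x_max,
            "y_max": d.box.y_max,
            "node_type": d.node_type.value,
            "score": d.score,
        }
        for d in detections
    ]
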