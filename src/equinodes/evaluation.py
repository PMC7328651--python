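"""Detection/annotation matching, confusion matrices, and derived metrics.

Detections are matched greedily (descending score) to annotations by IoU;
matched pairs feed the node-type confusion matrix, whose trace / total is
the cross-type accuracy. Image-level predictions feed a taxon confusion
matrix. False-positive / false-negative counts are computed but advisory
only: manual annotations of herbarium sheets are routinely incomplete, so
unmatched detections are often genuine nodes rather than errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .detector import iou
from .types import (
    AnnotationBox,
    Detection,
    NodeType,
    TaxonLabel,
    ValidationError,
)


@dataclass
class ConfusionMatrix:
    """Non-negative integer count grid with ordered axis labels."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match label lists")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(d["row_labels"], d["col_labels"], np.asarray(d["counts"]))


@dataclass
class MatchResult:
    """Greedy detection-annotation pairing for one image."""

    matched: list[tuple[Detection, AnnotationBox, float]] = field(default_factory=list)
    false_positives: list[Detection] = field(default_factory=list)
    false_negatives: list[AnnotationBox] = field(default_factory=list)


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest whole percent, halves away from zero."""
    return int(math.floor(fraction * 100 + 0.5))


def match_detections(
    detections: Sequence[Detection],
    annotations: Sequence[AnnotationBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching by descending detection score.

    Each detection (highest score first; ties by box coordinates) claims
    the still-unmatched annotation of highest IoU, provided that IoU is at
    least ``iou_threshold``. Unmatched detections are false positives,
    unmatched annotations false negatives.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].box.as_tuple()),
    )
    result = MatchResult()
    taken = [False] * len(annotations)
    for i in order:
        det = detections[i]
        best_j, best_iou = -1, 0.0
        for j, ann in enumerate(annotations):
            if taken[j]:
                continue
            v = iou(det.box, ann.box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            result.matched.append((det, annotations[best_j], best_iou))
        else:
            result.false_positives.append(det)
    result.false_negatives = [a for j, a in enumerate(annotations) if not taken[j]]
    return result


def proxy_type_pairs(
    matches: MatchResult, taxon: TaxonLabel, type_set: tuple[NodeType, ...]
) -> list[tuple[NodeType, NodeType]]:
    """(true type, detected type) pairs for one image's matched detections.

    The true type of every node is the proxy label implied by the image's
    taxon. In two-type mode, hybrid images have no defined true node type
    and are rejected.
    """
    true_type = NodeType.for_taxon(taxon)
    if true_type not in type_set:
        raise ValidationError(
            f"image taxon {taxon.value} has no true node type in mode {[t.value for t in type_set]}"
        )
    return [(true_type, det.node_type) for det, _, _ in matches.matched]


def node_confusion(
    pairs: Iterable[tuple[NodeType, NodeType]],
    type_set: tuple[NodeType, ...] = (NodeType.H, NodeType.L),
) -> ConfusionMatrix:
    """Counts of (true node type, detected node type) over matched pairs."""
    labels = [t.value for t in type_set]
    idx = {t: i for i, t in enumerate(type_set)}
    counts = np.zeros((len(type_set), len(type_set)), dtype=np.int64)
    for true_t, det_t in pairs:
        counts[idx[true_t], idx[det_t]] += 1
    return ConfusionMatrix(labels, labels, counts)


def cross_type_accuracy(m: ConfusionMatrix) -> float:
    """Fraction of matched nodes whose detected type equals the true type."""
    if m.counts.shape[0] != m.counts.shape[1]:
        raise ValidationError("cross-type accuracy needs a square matrix")
    if m.total == 0:
        raise ValidationError("cross-type accuracy undefined on an empty matrix")
    return float(np.trace(m.counts)) / m.total


def pairwise_confusion_rate(m: ConfusionMatrix, type_a: str, type_b: str) -> float:
    """How often two types are confused with each other.

    Restricted to entries whose true AND detected labels are both in
    ``{type_a, type_b}``: the fraction of those with true != detected.
    """
    for t in (type_a, type_b):
        if t not in m.row_labels or t not in m.col_labels:
            raise ValidationError(f"type {t!r} not present in matrix labels")
    ra, rb = m.row_labels.index(type_a), m.row_labels.index(type_b)
    ca, cb = m.col_labels.index(type_a), m.col_labels.index(type_b)
    sub = m.counts[np.ix_([ra, rb], [ca, cb])]
    total = sub.sum()
    if total == 0:
        return 0.0
    return float(sub[0, 1] + sub[1, 0]) / float(total)


def taxon_confusion(
    true_labels: Sequence[TaxonLabel | str], predicted_labels: Sequence[TaxonLabel | str]
) -> ConfusionMatrix:
    """3x3 image-level confusion matrix in fixed taxon order."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists must have equal length")
    order = [t.value for t in TaxonLabel]
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        tv = t.value if isinstance(t, TaxonLabel) else str(t)
        pv = p.value if isinstance(p, TaxonLabel) else str(p)
        if tv not in order or pv not in order:
            raise ValidationError(f"label outside taxon set: {tv!r} / {pv!r}")
        counts[order.index(tv), order.index(pv)] += 1
    return ConfusionMatrix(order, order, counts)


def image_accuracy(m: ConfusionMatrix) -> float:
    """Fraction of images classified into their true taxon."""
    if m.total == 0:
        raise ValidationError("accuracy undefined on an empty matrix")
    return float(np.trace(m.counts)) / m.total


def evaluate_detections(
    per_image: dict[str, tuple[Sequence[Detection], Sequence[AnnotationBox], TaxonLabel]],
    type_set: tuple[NodeType, ...] = (NodeType.H, NodeType.L),
    iou_threshold: float = 0.5,
) -> dict:
    """Node-level evaluation over a test set.

    ``per_image`` maps image_id to (detections, node annotations, taxon).
    Images whose taxon has no proxy type in ``type_set`` (hybrids in
    two-type mode) are skipped for the confusion matrix but still counted
    in the advisory FP/FN totals.
    """
    pairs = []
    n_fp = n_fn = n_matched = 0
    for image_id, (dets, anns, taxon) in sorted(per_image.items()):
        mr = match_detections(dets, anns, iou_threshold)
        n_fp += len(mr.false_positives)
        n_fn += len(mr.false_negatives)
        n_matched += len(mr.matched)
        if NodeType.for_taxon(taxon) in type_set:
            pairs.extend(proxy_type_pairs(mr, taxon, type_set))
    cm = node_confusion(pairs, type_set)
    return {
        "node_confusion": cm,
        "cross_type_accuracy": cross_type_accuracy(cm) if cm.total else None,
        "n_matched_typed": cm.total,
        "n_matched_all": n_matched,
        "false_positives_advisory": n_fp,
        "false_negatives_advisory": n_fn,
        "iou_threshold": iou_threshold,
    }
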