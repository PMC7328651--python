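"""Per-image detection statistics: the classifier's feature vector.

For each image the detector's output is condensed into the averages of the
10 top-scoring detections of each node type — ``a_H`` and ``a_L`` (plus
``a_F`` in the three-type experiment). These averages are the only
information the taxon classifier sees. Scores may also be quantized to an
integer 0–10 scale for display (a score of 0.73 prints as 7); quantization
is display-only and never feeds computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Detection, NodeType, ValidationError

DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class ImageStatistics:
    """Top-k score averages per node type, with contributing counts.

    ``a_F``/``n_F`` are ``None``/0 in the two-type mode. An average of 0
    with count 0 encodes "no detection of that type".
    """

    a_H: float
    a_L: float
    n_H: int
    n_L: int
    a_F: Optional[float] = None
    n_F: int = 0

    def vector(self) -> np.ndarray:
        if self.a_F is None:
            return np.array([self.a_H, self.a_L])
        return np.array([self.a_H, self.a_L, self.a_F])

    @property
    def feature_names(self) -> list[str]:
        return ["a_H", "a_L"] if self.a_F is None else ["a_H", "a_L", "a_F"]


def quantize_score(score: float) -> int:
    """Quantize a confidence in [0, 1] to the integer 0–10 display scale.

    Multiplies by ten and rounds to the nearest integer, halves away from
    zero (0.65 -> 7). Display-only.
    """
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must lie in [0, 1], got {score}")
    return int(math.floor(score * 10 + 0.5))


def top_k_mean(
    detections: Sequence[Detection], node_type: NodeType, k: int = DEFAULT_TOP_K
) -> tuple[float, int]:
    """Mean score of the k top-scoring detections of one type.

    Fewer than ``k`` detections of the type: the mean is over those
    available. None at all: ``(0.0, 0)``.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    scores = sorted((d.score for d in detections if d.node_type == node_type), reverse=True)
    top = scores[:k]
    if not top:
        return 0.0, 0
    return float(np.mean(top)), len(top)


def image_features(
    detections: Sequence[Detection],
    type_set: tuple[NodeType, ...] = (NodeType.H, NodeType.L),
    k: int = DEFAULT_TOP_K,
    variant: str = "means",
    pad_to_k: bool = False,
):
    """Condense one image's detections into classifier features.

    variant='means' (the default, and empirically the strongest choice)
    returns :class:`ImageStatistics`. variant='ratio' returns
    ``{'ratio': a_H / a_L, 'ratio_defined': bool}`` with a NaN sentinel when
    ``a_L`` is 0. variant='stds' returns the standard deviations of the same
    top-k score sets. ``pad_to_k`` treats missing detections as zero scores
    (averaging over exactly k), for sensitivity analysis.
    """
    if variant not in ("means", "ratio", "stds"):
        raise ValidationError(f"unknown variant {variant!r}; use means, ratio or stds")

    def stat(node_type: NodeType) -> tuple[float, int]:
        mean, n = top_k_mean(detections, node_type, k)
        if pad_to_k and n:
            mean = mean * n / k
        return mean, n

    if variant == "means":
        (a_h, n_h), (a_l, n_l) = stat(NodeType.H), stat(NodeType.L)
        if NodeType.F in type_set:
            a_f, n_f = stat(NodeType.F)
            return ImageStatistics(a_H=a_h, a_L=a_l, n_H=n_h, n_L=n_l, a_F=a_f, n_F=n_f)
        return ImageStatistics(a_H=a_h, a_L=a_l, n_H=n_h, n_L=n_l)

    if variant == "ratio":
        (a_h, _), (a_l, _) = stat(NodeType.H), stat(NodeType.L)
        if a_l == 0.0:
            return {"ratio": math.nan, "ratio_defined": False}
        return {"ratio": a_h / a_l, "ratio_defined": True}

    # variant == "stds"
    out = {}
    for t in type_set:
        scores = sorted((d.score for d in detections if d.node_type == t), reverse=True)[:k]
        if pad_to_k:
            scores = scores + [0.0] * (k - len(scores))
        out[f"s_{t.value}"] = float(np.std(scores)) if scores else 0.0
    return out


def features_to_frame(
    stats: dict[str, ImageStatistics], taxa: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Tabulate per-image statistics for CSV export (sorted by image_id)."""
    rows = []
    for image_id in sorted(stats):
        s = stats[image_id]
        rows.append(
            {
                "image_id": image_id,
                "a_H": s.a_H,
                "a_L": s.a_L,
                "a_F": s.a_F if s.a_F is not None else "",
                "n_H": s.n_H,
                "n_L": s.n_L,
                "n_F": s.n_F,
                "taxon": (taxa or {}).get(image_id, ""),
            }
        )
    return pd.DataFrame(rows)
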