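"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open pixel boxes ``[x_min, x_max) x
[y_min, y_max)`` with the origin at the top-left corner of the image.
VIA stores rectangles as (x, y, width, height); they are converted to
half-open boxes at read time and kept as floats until rasterization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "BoundingBox",
    "Category",
    "AnnotationBox",
    "TaxonLabel",
    "NodeType",
    "AnnotatedImage",
    "DatasetSplit",
    "Detection",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle ``[x_min, x_max) x [y_min, y_max)`` in pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"box coordinates must be finite, got {vals}")
        if min(vals) < 0:
            raise ValidationError(f"box coordinates must be >= 0, got {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"box must have positive extent: {vals}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clip(self, width: float, height: float) -> Optional["BoundingBox"]:
        """Clip to ``[0, width) x [0, height)``; None if nothing remains."""
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, float(width))
        y1 = min(self.y_max, float(height))
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


class Category(str, enum.Enum):
    """The four structural categories used in the manual annotations."""

    STROBILUS = "strobilus"
    NORMAL_STEM_NODE = "normal_stem_node"
    NORMAL_STEM_INTERNODE = "normal_stem_internode"
    INJURED_STEM_NODE = "injured_stem_node"


#: VIA files in the wild write categories with spaces; accept both spellings.
_CATEGORY_ALIASES = {c.value: c for c in Category} | {
    c.value.replace("_", " "): c for c in Category
}


def parse_category(raw: str) -> Category:
    try:
        return _CATEGORY_ALIASES[raw.strip().lower()]
    except KeyError:
        allowed = sorted({c.value for c in Category})
        raise ValidationError(
            f"unknown category {raw!r}; allowed categories: {allowed}"
        ) from None


@dataclass(frozen=True)
class AnnotationBox:
    box: BoundingBox
    category: Category


class TaxonLabel(str, enum.Enum):
    HYEMALE = "hyemale"
    LAEVIGATUM = "laevigatum"
    FERRISSII = "ferrissii"


def parse_taxon(raw: str) -> TaxonLabel:
    try:
        return TaxonLabel(raw.strip().lower())
    except ValueError:
        allowed = [t.value for t in TaxonLabel]
        raise ValidationError(
            f"unknown taxon {raw!r}; allowed taxa: {allowed}"
        ) from None


class NodeType(str, enum.Enum):
    """Node appearance class, proxy-labeled by the taxon of the source image."""

    H = "H"  # hyemale-type: dark/light/dark cross-banding
    L = "L"  # laevigatum-type: green sheath with a narrow black rim
    F = "F"  # ferrissii-type, only in the three-node-type experiment

    @staticmethod
    def for_taxon(taxon: TaxonLabel) -> "NodeType":
        return {
            TaxonLabel.HYEMALE: NodeType.H,
            TaxonLabel.LAEVIGATUM: NodeType.L,
            TaxonLabel.FERRISSII: NodeType.F,
        }[taxon]


@dataclass
class AnnotatedImage:
    """An image together with its box annotations and optional taxon label.

    ``image`` may be None when annotations are handled without pixels
    (e.g. when only the VIA project file is available).
    """

    image_id: str
    annotations: list[AnnotationBox] = field(default_factory=list)
    image: Optional[np.ndarray] = None  # uint8, H x W x 3
    taxon: Optional[TaxonLabel] = None

    def with_(self, **kwargs) -> "AnnotatedImage":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        groups = (set(self.train), set(self.validation), set(self.test))
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValidationError("split groups must be pairwise disjoint")

    def subset_of(self, split: str) -> tuple[str, ...]:
        return {"train": self.train, "validation": self.validation, "test": self.test}[split]


@dataclass(frozen=True)
class Detection:
    """Detector output: a box, a node type, and a confidence in [0, 1]."""

    box: BoundingBox
    node_type: NodeType
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")
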