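"""Reading and writing VIA v2 project JSON, image manifests, and splits.

The VGG Image Annotator (VIA) v2 project format stores, per image, a list
of regions; each rectangle region carries ``shape_attributes``
(name="rect", x, y, width, height) and ``region_attributes`` with the
structural category. Taxon labels have no slot in VIA, so they live in a
sidecar manifest CSV with columns ``image_id, taxon[, split]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    AnnotatedImage,
    AnnotationBox,
    BoundingBox,
    DatasetSplit,
    TaxonLabel,
    ValidationError,
    parse_category,
    parse_taxon,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("image_id", "taxon", "split")


def _via_key(image_id: str, size: int = -1) -> str:
    # VIA keys entries by filename + file size; size -1 marks "unknown".
    return f"{image_id}{size}"


def read_via(path: str | Path, images_dir: Optional[str | Path] = None) -> list[AnnotatedImage]:
    """Read a VIA v2 project JSON file.

    Parameters
    ----------
    path
        VIA project file (either a full project with ``_via_img_metadata``
        or a bare metadata dictionary, both of which VIA exports).
    images_dir
        If given, image pixels are loaded from ``images_dir / filename``
        and boxes extending past the image bounds are clipped (with a
        warning); otherwise pixel data stays ``None`` and boxes are kept
        as stored.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed VIA JSON in {path}: {exc}") from exc

    metadata = raw.get("_via_img_metadata", raw)
    if not isinstance(metadata, dict):
        raise ValidationError(f"malformed VIA project {path}: '_via_img_metadata' is not an object")

    images: list[AnnotatedImage] = []
    for key, entry in metadata.items():
        if not isinstance(entry, dict) or "filename" not in entry:
            raise ValidationError(f"malformed VIA entry under key {key!r}: missing 'filename'")
        image_id = entry["filename"]

        pixels = None
        if images_dir is not None:
            img_path = Path(images_dir) / image_id
            pixels = np.asarray(Image.open(img_path).convert("RGB"), dtype=np.uint8)

        annotations: list[AnnotationBox] = []
        for region in entry.get("regions", []):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "rect":
                raise ValidationError(
                    f"region of shape {shape.get('name')!r} in {image_id}: only 'rect' regions are supported"
                )
            try:
                x, y = float(shape["x"]), float(shape["y"])
                w, h = float(shape["width"]), float(shape["height"])
            except KeyError as exc:
                raise ValidationError(f"malformed rect region in {image_id}: missing key {exc}") from exc
            box = BoundingBox(x, y, x + w, y + h)
            if pixels is not None:
                height, width = pixels.shape[:2]
                clipped = box.clip(width, height)
                if clipped is None:
                    warnings.warn(f"{image_id}: box {box.as_tuple()} lies outside image; dropped")
                    continue
                if clipped != box:
                    logger.warning("%s: box %s clipped to image bounds", image_id, box.as_tuple())
                    box = clipped
            category = parse_category(region.get("region_attributes", {}).get("category", ""))
            annotations.append(AnnotationBox(box=box, category=category))

        images.append(AnnotatedImage(image_id=image_id, annotations=annotations, image=pixels))
    return images


def write_via(images: Sequence[AnnotatedImage], path: str | Path) -> None:
    """Write annotations as VIA v2 project JSON, re-readable by :func:`read_via`."""
    metadata = {}
    for img in images:
        regions = [
            {
                "shape_attributes": {
                    "name": "rect",
                    "x": ann.box.x_min,
                    "y": ann.box.y_min,
                    "width": ann.box.width,
                    "height": ann.box.height,
                },
                "region_attributes": {"category": ann.category.value},
            }
            for ann in img.annotations
        ]
        metadata[_via_key(img.image_id)] = {
            "filename": img.image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    project = {
        "_via_settings": {"project": {"name": "equinodes"}},
        "_via_img_metadata": metadata,
        "_via_attributes": {
            "region": {
                "category": {
                    "type": "dropdown",
                    "options": {
                        "strobilus": "",
                        "normal_stem_node": "",
                        "normal_stem_internode": "",
                        "injured_stem_node": "",
                    },
                }
            }
        },
    }
    Path(path).write_text(json.dumps(project, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sidecar manifest CSV (image_id, taxon[, split])."""
    df = pd.read_csv(path, dtype=str)
    missing = {"image_id", "taxon"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path} is missing columns: {sorted(missing)}")
    df["taxon"] = [parse_taxon(t).value for t in df["taxon"]]
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def attach_taxa(images: Iterable[AnnotatedImage], manifest: pd.DataFrame) -> list[AnnotatedImage]:
    taxa = dict(zip(manifest["image_id"], manifest["taxon"]))
    out = []
    for img in images:
        taxon = taxa.get(img.image_id)
        out.append(img.with_(taxon=TaxonLabel(taxon) if taxon else img.taxon))
    return out


def split_dataset(
    image_ids: Sequence[str],
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int,
    taxa: Optional[Sequence[TaxonLabel | str]] = None,
) -> DatasetSplit:
    """Deterministic train/validation/test partition, stratified by taxon.

    Counts must sum to ``len(image_ids)``. When taxon labels are given,
    each split receives (as close as possible) equal per-taxon proportions;
    remainders are assigned in seeded order.
    """
    ids = list(image_ids)
    if min(n_train, n_val, n_test) < 0:
        raise ValidationError("split counts must be >= 0")
    if n_train + n_val + n_test != len(ids):
        raise ValidationError(
            f"split counts {n_train}+{n_val}+{n_test} != {len(ids)} image ids"
        )
    if len(set(ids)) != len(ids):
        raise ValidationError("image ids must be unique")

    rng = np.random.default_rng(seed)

    if taxa is None:
        groups = {None: ids}
    else:
        if len(taxa) != len(ids):
            raise ValidationError("taxa must align with image_ids")
        groups = {}
        for iid, taxon in zip(ids, taxa):
            key = taxon.value if isinstance(taxon, TaxonLabel) else str(taxon)
            groups.setdefault(key, []).append(iid)

    n = len(ids)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    # leftovers after per-group proportional allocation, filled by seeded order
    pool: list[str] = []
    for key in sorted(groups, key=str):
        members = list(groups[key])
        rng.shuffle(members)
        g_train = int(np.floor(n_train * len(members) / n)) if n else 0
        g_val = int(np.floor(n_val * len(members) / n)) if n else 0
        g_test = int(np.floor(n_test * len(members) / n)) if n else 0
        train.extend(members[:g_train])
        val.extend(members[g_train : g_train + g_val])
        test.extend(members[g_train + g_val : g_train + g_val + g_test])
        pool.extend(members[g_train + g_val + g_test :])

    rng.shuffle(pool)
    for iid in pool:
        if len(train) < n_train:
            train.append(iid)
        elif len(val) < n_val:
            val.append(iid)
        else:
            test.append(iid)

    return DatasetSplit(tuple(train), tuple(val), tuple(test), seed=seed)
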