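"""End-to-end orchestration: generate -> split -> train -> detect ->
features -> classify -> evaluate.

The two-type mode mirrors the main experiment: the detector learns H vs L
nodes exclusively from hyemale and laevigatum specimens, hybrid images are
only seen at classification time, and the image classifier (5-nn by
default) works on (a_H, a_L). The three-type mode re-trains the detector
with an F class for hybrid-image nodes and classifies on (a_H, a_L, a_F)
with a shallow decision tree by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, classifiers, detector, evaluation, node_statistics, synthetic
from .augmentation import AugmentationConfig
from .detector import AnchorSpec, TrainingConfig
from .synthetic import SyntheticParams
from .types import AnnotatedImage, NodeType, TaxonLabel, ValidationError

logger = logging.getLogger(__name__)

MODES = ("two_type", "three_type")
TYPE_SETS = {
    "two_type": (NodeType.H, NodeType.L),
    "three_type": (NodeType.H, NodeType.L, NodeType.F),
}
DEFAULT_CLASSIFIER = {"two_type": "knn", "three_type": "tree"}


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, human-editable configuration for the whole pipeline."""

    mode: str = "two_type"
    seed: int = 0
    n_per_taxon: int = 36
    n_train: int = 54
    n_val: int = 24
    n_test: int = 30
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)
    anchor_spec: AnchorSpec = field(default_factory=AnchorSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    score_threshold: float = 0.3
    overlap_threshold: float = 0.3
    match_iou: float = 0.5
    top_k: int = 10
    classifier_variant: Optional[str] = None  # None -> mode default
    classifier_hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES + ("both",):
            raise ValidationError(f"mode must be one of {MODES + ('both',)}")
        if self.n_train + self.n_val + self.n_test != 3 * self.n_per_taxon:
            raise ValidationError("split counts must sum to 3 * n_per_taxon")
        for name in ("score_threshold", "overlap_threshold", "match_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("synthetic", SyntheticParams),
            ("anchor_spec", AnchorSpec),
            ("training", TrainingConfig),
            ("augmentation", AugmentationConfig),
        ):
            if key in d and isinstance(d[key], dict):
                kw = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = sub(**kw)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _detector_subset(images: list[AnnotatedImage], mode: str) -> list[AnnotatedImage]:
    if mode == "two_type":
        return [i for i in images if i.taxon != TaxonLabel.FERRISSII]
    return images


def run_mode(
    config: PipelineConfig,
    images: list[AnnotatedImage],
    split,
    mode: str,
    out_dir: Optional[Path] = None,
) -> dict:
    """Run detector training, detection, features, classification and
    evaluation for one mode on an already-generated dataset."""
    type_set = TYPE_SETS[mode]
    by_id = {img.image_id: img for img in images}
    t0 = time.time()

    det_train = _detector_subset([by_id[i] for i in split.train], mode)
    det_val = _detector_subset([by_id[i] for i in split.validation], mode)
    model, history = detector.train_detector(
        det_train,
        det_val,
        config.training,
        seed=config.seed,
        anchor_spec=config.anchor_spec,
        type_set=type_set,
        aug_config=config.augmentation,
    )
    logger.info("[%s] detector trained in %.1fs (val error %.4f)", mode, time.time() - t0, history["best_val_error"])

    detections = {}
    for img in images:
        detections[img.image_id] = detector.detect(
            model, img.image, config.score_threshold, config.overlap_threshold
        )

    stats = {
        iid: node_statistics.image_features(dets, type_set, k=config.top_k)
        for iid, dets in detections.items()
    }
    taxa = {img.image_id: img.taxon.value for img in images}
    features_frame = node_statistics.features_to_frame(stats, taxa)
    features_frame["split"] = [
        "train" if i in split.train else "validation" if i in split.validation else "test"
        for i in features_frame["image_id"]
    ]

    variant = config.classifier_variant or DEFAULT_CLASSIFIER[mode]
    train_ids = sorted(split.train)
    clf = classifiers.fit(
        [stats[i] for i in train_ids],
        [by_id[i].taxon for i in train_ids],
        variant=variant,
        hyperparams=config.classifier_hyperparams,
        seed=config.seed,
    )
    test_ids = sorted(split.test)
    predictions = classifiers.predict(clf, [stats[i] for i in test_ids])
    true_taxa = [by_id[i].taxon for i in test_ids]
    t_cm = evaluation.taxon_confusion(true_taxa, predictions)

    node_eval = evaluation.evaluate_detections(
        {
            i: (
                detections[i],
                [a for a in by_id[i].annotations if a.category in detector.NODE_CATEGORIES],
                by_id[i].taxon,
            )
            for i in test_ids
        },
        type_set,
        config.match_iou,
    )

    report = {
        "mode": mode,
        "classifier_variant": variant,
        "node_confusion": node_eval["node_confusion"].to_dict(),
        "cross_type_accuracy": node_eval["cross_type_accuracy"],
        "n_matched_typed": node_eval["n_matched_typed"],
        "false_positives_advisory": node_eval["false_positives_advisory"],
        "false_negatives_advisory": node_eval["false_negatives_advisory"],
        "taxon_confusion": t_cm.to_dict(),
        "image_accuracy": evaluation.image_accuracy(t_cm),
        "detector_val_error": history["best_val_error"],
        "detector_stopped_at": history["stopped_at"],
    }
    logger.info("[%s] mode finished in %.1fs", mode, time.time() - t0)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        features_frame.to_csv(out_dir / f"features_{mode}.csv", index=False)
        rows = []
        for iid in sorted(detections):
            rows.extend(detector.detections_to_rows(iid, detections[iid]))
        pd.DataFrame(
            rows, columns=["image_id", "x_min", "y_min", "x_max", "y_max", "node_type", "score"]
        ).to_csv(out_dir / f"detections_{mode}.csv", index=False)
        model.save(out_dir / f"detector_{mode}")
        clf.save(out_dir / f"classifier_{mode}.json")
        preds_frame = pd.DataFrame(
            {
                "image_id": test_ids,
                "predicted_taxon": [p.value for p in predictions],
                "true_taxon": [t.value for t in true_taxa],
            }
        )
        preds_frame.to_csv(out_dir / f"predictions_{mode}.csv", index=False)
    return report


def run(config: PipelineConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    out_path = Path(out_dir) if out_dir is not None else None
    t0 = time.time()
    images, manifest = synthetic.generate_dataset(
        config.n_per_taxon, config.synthetic, seed=config.seed
    )
    split = annotation_io.split_dataset(
        [i.image_id for i in images],
        config.n_train,
        config.n_val,
        config.n_test,
        seed=config.seed,
        taxa=[i.taxon for i in images],
    )
    logger.info("generated %d images in %.1fs", len(images), time.time() - t0)

    modes = MODES if config.mode == "both" else (config.mode,)
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "split": {
            "train": list(split.train),
            "validation": list(split.validation),
            "test": list(split.test),
        },
        "modes": {},
    }
    for mode in modes:
        try:
            report["modes"][mode] = run_mode(config, images, split, mode, out_path)
        except Exception:
            if out_path is not None:
                (out_path / "report_partial.json").write_text(
                    json.dumps(report, indent=1, default=str)
                )
            logger.exception("pipeline stage failed in mode %s", mode)
            raise

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        manifest_split = manifest.copy()
        manifest_split["split"] = [
            "train" if i in split.train else "validation" if i in split.validation else "test"
            for i in manifest_split["image_id"]
        ]
        annotation_io.write_manifest(manifest_split, out_path / "manifest.csv")
        (out_path / "report.json").write_text(json.dumps(report, indent=1, default=str))
        (out_path / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of a pipeline report."""
    from .evaluation import ConfusionMatrix

    lines = [
        f"config hash : {report['config_hash']}",
        f"seed        : {report['seed']}",
    ]
    for mode, r in report["modes"].items():
        lines.append("")
        lines.append(f"=== mode: {mode} (classifier: {r['classifier_variant']}) ===")
        ncm = ConfusionMatrix.from_dict(r["node_confusion"])
        lines.append("node confusion (rows: true type, cols: detected type):")
        lines.append(ncm.to_frame().to_string())
        if r["cross_type_accuracy"] is not None:
            lines.append(
                f"cross-type accuracy: {r['cross_type_accuracy']:.4f}"
                f" ({evaluation.round_percent(r['cross_type_accuracy'])}%)"
                f" over {r['n_matched_typed']} matched nodes"
            )
        tcm = ConfusionMatrix.from_dict(r["taxon_confusion"])
        lines.append("taxon confusion (rows: true, cols: predicted):")
        lines.append(tcm.to_frame().to_string())
        lines.append(
            f"image accuracy: {r['image_accuracy']:.4f}"
            f" ({evaluation.round_percent(r['image_accuracy'])}%)"
        )
    return "\n".join(lines) + "\n"
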