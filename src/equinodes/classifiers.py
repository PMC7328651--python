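"""Image-level taxon classifiers over the detection-score features.

Three small-sample classifiers operate on the per-image feature vector
(a_H, a_L[, a_F]): multinomial logistic regression (straight-line
boundaries in the feature plane), a shallow decision tree (axis-aligned
threshold questions "is a_L (or a_H) greater than t?"), and a k-nearest-
neighbor vote with k = 5 by default. Logistic and tree models are fitted
with scikit-learn; prediction always runs off the serialized parameter
representation so that models round-trip losslessly through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .node_statistics import ImageStatistics
from .types import TaxonLabel, ValidationError

TAXON_ORDER = [t.value for t in TaxonLabel]

Features = Union[Sequence[ImageStatistics], np.ndarray]


def _as_matrix(features: Features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, np.ndarray):
        X = np.atleast_2d(features).astype(float)
        names = ["a_H", "a_L", "a_F"][: X.shape[1]]
        return X, names
    stats = list(features)
    if not stats:
        raise ValidationError("empty feature list")
    names = stats[0].feature_names
    if any(s.feature_names != names for s in stats):
        raise ValidationError("features mix two-type and three-type statistics")
    return np.stack([s.vector() for s in stats]), names


@dataclass
class ClassifierModel:
    """A fitted taxon classifier with a JSON-serializable parameterization."""

    variant: str  # "logistic" | "tree" | "knn"
    feature_names: list[str]
    classes: list[str]
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "variant": self.variant,
            "feature_names": self.feature_names,
            "classes": self.classes,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


DEFAULT_HYPERPARAMS = {
    "logistic": {"C": 10.0, "max_iter": 2000},
    "tree": {"max_depth": 3, "min_samples_leaf": 2},
    "knn": {"k": 5},
}


def fit(
    features: Features,
    labels: Sequence[TaxonLabel | str],
    variant: str = "knn",
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit one classifier variant on per-image statistics.

    Logistic regression uses a multinomial model with mild L2
    regularization (unregularized fits may not converge on separable
    desk-scale data); the tree uses Gini impurity with shallow depth and a
    minimum leaf size, since 30-point training sets demand strong
    regularization; knn memorizes the training pairs. Features are not
    scaled: all statistics already share the [0, 1] scale.
    """
    if variant not in DEFAULT_HYPERPARAMS:
        raise ValidationError(f"unknown classifier variant {variant!r}")
    hp = {**DEFAULT_HYPERPARAMS[variant], **(hyperparams or {})}
    X, names = _as_matrix(features)
    y = np.array([l.value if isinstance(l, TaxonLabel) else str(l) for l in labels])
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")

    present = sorted(set(y), key=TAXON_ORDER.index)
    if variant in ("logistic", "tree") and len(present) < 2:
        raise ValidationError(f"{variant} requires at least two classes in training data")
    if variant == "knn" and not (1 <= hp["k"] <= X.shape[0]):
        raise ValidationError(f"knn requires 1 <= k <= n_train, got k={hp['k']}, n={X.shape[0]}")

    if variant == "logistic":
        clf = LogisticRegression(C=hp["C"], max_iter=hp["max_iter"], random_state=seed)
        clf.fit(X, y)
        params = {
            "coef": clf.coef_.tolist(),
            "intercept": clf.intercept_.tolist(),
            "coef_classes": list(clf.classes_),
        }
        return ClassifierModel("logistic", names, present, params)

    if variant == "tree":
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
        )
        clf.fit(X, y)
        t = clf.tree_
        leaf_class = [str(clf.classes_[np.argmax(v[0])]) for v in t.value]
        params = {
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "leaf_class": leaf_class,
        }
        return ClassifierModel("tree", names, present, params)

    # knn
    return ClassifierModel(
        "knn",
        names,
        present,
        {"k": int(hp["k"]), "X": X.tolist(), "y": y.tolist()},
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(model: ClassifierModel, features: Features) -> list[TaxonLabel]:
    """Deterministic taxon predictions for one or more feature vectors."""
    X, names = _as_matrix(features)
    if X.shape[1] != len(model.feature_names):
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match model ({len(model.feature_names)})"
        )
    p = model.params

    if model.variant == "logistic":
        coef = np.asarray(p["coef"], dtype=float)
        intercept = np.asarray(p["intercept"], dtype=float)
        if coef.shape[0] == 1:  # sklearn binary convention
            z = X @ coef[0] + intercept[0]
            scores = np.stack([-z, z], axis=1)
        else:
            scores = X @ coef.T + intercept
        idx = _softmax(scores).argmax(axis=1)
        out = [p["coef_classes"][i] for i in idx]

    elif model.variant == "tree":
        left = p["children_left"]
        right = p["children_right"]
        feat = p["feature"]
        thr = p["threshold"]
        leaf = p["leaf_class"]
        out = []
        for row in X:
            node = 0
            while left[node] != -1:
                node = left[node] if row[feat[node]] <= thr[node] else right[node]
            out.append(leaf[node])

    else:  # knn: Euclidean, majority vote; ties -> smallest mean distance,
        # then fixed taxon order
        Xt = np.asarray(p["X"], dtype=float)
        yt = np.asarray(p["y"])
        k = p["k"]
        out = []
        for row in X:
            d = np.sqrt(((Xt - row) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[:k]
            votes: dict[str, list[float]] = {}
            for i in nn:
                votes.setdefault(str(yt[i]), []).append(float(d[i]))
            out.append(
                min(
                    votes,
                    key=lambda c: (-len(votes[c]), float(np.mean(votes[c])), TAXON_ORDER.index(c)),
                )
            )
    return [TaxonLabel(v) for v in out]


def cross_validate(
    features: Features,
    labels: Sequence[TaxonLabel | str],
    variant_grid: Optional[dict[str, tuple[str, dict]]] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold accuracy for each classifier variant.

    ``variant_grid`` maps a display name to ``(variant, hyperparams)``; the
    default grid compares logistic, the shallow tree, and knn at several k.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    X, _ = _as_matrix(features)
    y = np.array([l.value if isinstance(l, TaxonLabel) else str(l) for l in labels])
    counts = pd.Series(y).value_counts()
    if n_folds > counts.min():
        raise ValidationError(
            f"n_folds={n_folds} exceeds smallest class count ({counts.min()})"
        )
    if variant_grid is None:
        variant_grid = {
            "logistic": ("logistic", {}),
            "tree": ("tree", {}),
            **{f"knn_k{k}": ("knn", {"k": k}) for k in (1, 3, 5, 7)},
        }

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for name, (variant, hp) in variant_grid.items():
        accs = []
        for tr, te in folds:
            model = fit(X[tr], y[tr], variant=variant, hyperparams=hp, seed=seed)
            pred = predict(model, X[te])
            accs.append(float(np.mean([p.value == t for p, t in zip(pred, y[te])])))
        rows.append(
            {"name": name, "variant": variant, "hyperparams": json.dumps(hp), "mean_accuracy": float(np.mean(accs))}
        )
    return pd.DataFrame(rows)
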