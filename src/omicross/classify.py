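"""Subtype-classification evaluation protocol, generic over a backend.

The protocol — stratified 60/40 split, 10-fold cross-validated accuracy,
ROC/AUC on the held-out samples, feature-importance ranking, and the
intersection of feature genes with DEGs (the "DEFGs") — is fixed here; the
classifier itself is injected through a three-method contract (fit / score /
importance) so any tree ensemble or linear model can stand behind it.

Two backends ship: a deterministic centroid-logistic stub used throughout the
tests, and a gradient-boosted tree backend (xgboost) configured by default
with max_depth=14, 2000 rounds, gamma=1, min_child_weight=1.
"""

from __future__ import annotations

import warnings
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .datatypes import InputError, gene_layer


@runtime_checkable
class ClassifierBackend(Protocol):
    """Minimal contract: binary classifier with probabilities and importances."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ClassifierBackend": ...

    def score_samples(self, features: np.ndarray) -> np.ndarray:
        """Per-sample probability of class 2 (the second label level), in [0, 1]."""
        ...

    def importance(self) -> np.ndarray:
        """Per-feature nonnegative weight, length = feature count."""
        ...


class CentroidLogisticBackend:
    """Deterministic stub: logistic score of the difference of class-centroid
    projections.  Importance is |centroid difference| per feature."""

    def __init__(self, scale: float = 1.0):
        self.scale = scale
        self._w: np.ndarray | None = None
        self._b: float = 0.0

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "CentroidLogisticBackend":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) != 2:
            raise InputError("backend is binary")
        c1 = features[labels == classes[0]].mean(axis=0)
        c2 = features[labels == classes[1]].mean(axis=0)
        self._w = (c2 - c1) * self.scale
        mid = (c1 + c2) / 2.0
        self._b = -float(self._w @ mid)
        return self

    def score_samples(self, features: np.ndarray) -> np.ndarray:
        z = features @ self._w + self._b
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def importance(self) -> np.ndarray:
        return np.abs(self._w)


class XGBoostBackend:
    """Gradient-boosted trees behind the backend contract.

    Defaults follow the reference protocol (gamma=1, min_child_weight=1,
    max_depth=14, 2000 rounds); pass ``n_estimators`` to trade accuracy for
    speed on small problems.
    """

    def __init__(self, n_estimators: int = 2000, max_depth: int = 14,
                 gamma: float = 1.0, min_child_weight: float = 1.0,
                 seed: int = 0, **kwargs):
        from xgboost import XGBClassifier

        self._clf = XGBClassifier(
            n_estimators=n_estimators, max_depth=max_depth, gamma=gamma,
            min_child_weight=min_child_weight, random_state=seed,
            n_jobs=1, eval_metric="logloss", **kwargs)
        self._classes: np.ndarray | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "XGBoostBackend":
        labels = np.asarray(labels)
        self._classes = np.unique(labels)
        self._clf.fit(features, (labels == self._classes[1]).astype(int))
        return self

    def score_samples(self, features: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(features)[:, 1]

    def importance(self) -> np.ndarray:
        return np.asarray(self._clf.feature_importances_, dtype=float)


# ---------------------------------------------------------------- protocol

def stratified_split(samples: pd.Index | list, labels: pd.Series | np.ndarray,
                     train_frac: float = 0.6, seed: int = 0) -> tuple[list, list]:
    """Per-class proportional train/test split (largest-remainder rounding).

    Disjoint and exhaustive; deterministic given the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise InputError("train_frac must be in (0, 1)")
    samples = list(samples)
    labels = np.asarray(pd.Series(labels).reindex(samples)
                        if isinstance(labels, pd.Series) else labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise InputError("need two classes with >= 2 samples each")
    # largest-remainder allocation of the total train size across classes
    total_train = train_frac * len(samples)
    raw = counts * train_frac
    base = np.floor(raw).astype(int)
    remainder = raw - base
    extra = int(round(total_train)) - base.sum()
    order = np.argsort(-remainder)
    for i in range(max(extra, 0)):
        base[order[i % len(classes)]] += 1
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cls, n_train in zip(classes, base):
        idx = [s for s, l in zip(samples, labels) if l == cls]
        perm = rng.permutation(len(idx))
        train += [idx[i] for i in perm[:n_train]]
        test += [idx[i] for i in perm[n_train:]]
    return train, test


def cross_validate(backend_factory, features: np.ndarray, labels: np.ndarray,
                   folds: int = 10, seed: int = 0, threshold: float = 0.5) -> float:
    """Mean accuracy over stratified K folds at the given score threshold.

    ``backend_factory`` is called per fold and must return a fresh backend.
    Folds missing a class are skipped with a warning.
    """
    labels = np.asarray(labels)
    if folds > len(labels):
        raise InputError("more folds than samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = np.unique(labels)
    accs = []
    for tr, te in skf.split(features, labels):
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 1:
            warnings.warn("fold without both classes skipped", stacklevel=2)
            continue
        backend = backend_factory().fit(features[tr], labels[tr])
        scores = backend.score_samples(features[te])
        pred = np.where(scores >= threshold, classes[1], classes[0])
        accs.append(float(np.mean(pred == labels[te])))
    if not accs:
        raise InputError("no usable folds")
    return float(np.mean(accs))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC (ties count half, Mann-Whitney form).

    ``labels`` may be any two-level coding; the larger level is the positive
    class.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise InputError("ROC needs both classes present")
    y = (labels == classes[1]).astype(int)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, float))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(_trapezoid_auc(fpr, tpr))


def select_feature_genes(backend: ClassifierBackend, feature_names: list[str]) -> list[str]:
    """Feature genes: importance > 0, descending, ties broken by gene ID."""
    imp = np.asarray(backend.importance(), dtype=float)
    if len(imp) != len(feature_names):
        raise InputError("importance length != feature count")
    if (imp < 0).any():
        raise InputError("importances must be nonnegative")
    if not (imp > 0).any():
        warnings.warn("all importances are zero; no feature genes", stacklevel=2)
        return []
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], feature_names[i]))
    return [feature_names[i] for i in order if imp[i] > 0]


def defg_intersect(feature_genes: list[str], degs: list[str]) -> dict[str, list[str]]:
    """DEFGs: feature genes that are also DEGs, partitioned by omics layer."""
    common = set(feature_genes) & set(degs)
    if not common:
        warnings.warn("feature genes and DEGs are disjoint", stacklevel=2)
    out: dict[str, list[str]] = {"mRNA": [], "miRNA": [], "lncRNA": []}
    # preserve the feature-importance ordering within each layer
    for g in feature_genes:
        if g in common:
            out[gene_layer(g)].append(g)
    return out
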