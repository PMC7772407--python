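"""Confusion-matrix metrics and stratified 10-fold cross-validation.

Metrics are SN (recall), SP, ACC, MCC, Precision and F1, with bounded
conventions at zero denominators (MCC -> 0, Precision/F1 -> 0).
Cross-validation pools the per-fold predictions and computes one metrics
report; SMOTE placement is configurable:

``train_only``  balance each training fold, test on untouched held-out data
                (no synthetic sample ever reaches a test fold);
``global``      balance the full dataset first, then fold — the literal
                reading of pipelines that report metrics on augmented data;
``off``         no balancing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cart import TreeConfig, grow_tree, predict
from .resampling import SmoteConfig, balance_dataset

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "FoldAssignment",
    "confusion_matrix",
    "compute_metrics",
    "stratified_folds",
    "cross_validate",
    "SMOTE_MODES",
]

SMOTE_MODES = ("train_only", "global", "off")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    SN: float
    SP: float
    ACC: float
    MCC: float
    Precision: float
    F1: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class FoldAssignment:
    assignments: np.ndarray  # fold index in 1..k per sample
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Counts with label 1 as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {0, 1}
    if bad:
        raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = (tp + tn) / cm.total
    precision = ratio(tp, tp + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    den = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den > 0 else 0.0
    return MetricsReport(SN=sn, SP=sp, ACC=acc, MCC=mcc, Precision=precision, F1=f1)


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Class-wise shuffled round-robin assignment into folds 1..k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    assignments = np.zeros(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} samples; lower k (got k={k})"
            )
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(len(idx)) % k + 1
    return FoldAssignment(assignments=assignments, k=k, seed=seed)


def cross_validate(
    values: np.ndarray,
    labels: np.ndarray,
    feature_indices: Sequence[int] | None = None,
    tree_config: TreeConfig | None = None,
    smote_mode: str = "train_only",
    k: int = 10,
    fold_seed: int = 0,
    smote_config: SmoteConfig | None = None,
) -> MetricsReport:
    """Pooled k-fold CV of a CART classifier on a feature subset."""
    if smote_mode not in SMOTE_MODES:
        raise ValueError(f"smote_mode must be one of {SMOTE_MODES}, got {smote_mode!r}")
    tree_config = tree_config or TreeConfig()
    smote_config = smote_config or SmoteConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    X = values if feature_indices is None else values[:, list(feature_indices)]

    if smote_mode == "global":
        X, y, _ = balance_dataset(X, labels, smote_config)
    else:
        y = labels

    folds = stratified_folds(y, k=k, seed=fold_seed)
    pooled_pred = np.full(len(y), -1, dtype=int)
    for fold in range(1, k + 1):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        X_tr, y_tr = X[tr], y[tr]
        if smote_mode == "train_only":
            fold_cfg = SmoteConfig(
                k_neighbors=smote_config.k_neighbors,
                seed=smote_config.seed + fold,
            )
            X_tr, y_tr, _ = balance_dataset(X_tr, y_tr, fold_cfg)
        model = grow_tree(X_tr, y_tr, tree_config)
        pooled_pred[te] = predict(model, X[te])

    if np.any(pooled_pred < 0):
        raise RuntimeError("cross-validation failed to cover every sample")
    return compute_metrics(confusion_matrix(y, pooled_pred))
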