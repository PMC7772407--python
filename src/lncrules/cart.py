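"""Binary CART: Gini-impurity decision trees with deterministic splitting.

Splits are exhaustive: every feature, every midpoint between consecutive
distinct sorted values. The split maximizing the weighted Gini decrease
wins; ties go to the lowest feature index, then the smallest threshold.
Samples route left when ``value <= threshold``. Leaves predict the majority
class, ties predicting label 0 (conservative for rare-positive data).

The builder presorts every feature once and partitions the sort orders down
the tree, so growing stays O(features * n) per level after the initial sort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TreeConfig",
    "TreeNode",
    "DecisionTreeModel",
    "gini_impurity",
    "find_best_split",
    "grow_tree",
    "predict_label",
    "predict",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TreeConfig:
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    seed: int = 0  # reserved; the default splitter is fully deterministic

    def __post_init__(self) -> None:
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")


@dataclass
class TreeNode:
    counts: tuple[int, int]  # (label 0, label 1) training samples at the node
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        n0, n1 = self.counts
        return 1 if n1 > n0 else 0  # ties -> negative class


@dataclass
class DecisionTreeModel:
    root: TreeNode
    feature_ids: list[str]
    class_totals: tuple[int, int]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def to_json(self, path: str | Path | None = None) -> dict:
        def encode(node: TreeNode) -> dict:
            d: dict = {"counts": list(node.counts)}
            if not node.is_leaf:
                d.update(
                    feature=node.feature,
                    threshold=node.threshold,
                    left=encode(node.left),
                    right=encode(node.right),
                )
            else:
                d["prediction"] = node.prediction
            return d

        doc = {
            "feature_ids": self.feature_ids,
            "class_totals": list(self.class_totals),
            "root": encode(self.root),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "DecisionTreeModel":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())

        def decode(d: dict) -> TreeNode:
            node = TreeNode(counts=tuple(d["counts"]))
            if "feature" in d:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = decode(d["left"])
                node.right = decode(d["right"])
            return node

        return cls(
            root=decode(doc["root"]),
            feature_ids=list(doc["feature_ids"]),
            class_totals=tuple(doc["class_totals"]),
        )


def gini_impurity(class_counts: Sequence[int]) -> float:
    """1 - sum of squared class frequencies; in [0, 0.5] for two classes."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0:
        raise ValueError("class counts must be >= 0")
    total = n0 + n1
    if total == 0:
        raise ValueError("gini impurity undefined for an empty node")
    p0 = n0 / total
    p1 = n1 / total
    return 1.0 - (p0 * p0 + p1 * p1)


def _best_split_sorted(
    X: np.ndarray,
    y: np.ndarray,
    sorted_idx: np.ndarray,
    min_samples_leaf: int,
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, decrease) given per-feature sort orders.

    ``sorted_idx`` is (n, d): column j holds the node's sample indices
    ordered by feature j. Returns None when no admissible split decreases
    the impurity.
    """
    n, d = sorted_idx.shape
    if n < 2:
        return None
    vals = X[sorted_idx, np.arange(d)[None, :]]
    ys = y[sorted_idx]

    total_pos = int(y[sorted_idx[:, 0]].sum())
    total = n
    parent = gini_impurity((total - total_pos, total_pos))
    if parent == 0.0:
        return None

    left_pos = np.cumsum(ys, axis=0)[:-1].astype(float)  # splits after row i, i=1..n-1
    left_n = np.arange(1, n, dtype=float)[:, None]
    right_n = total - left_n
    right_pos = total_pos - left_pos

    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = (
            left_pos * (left_n - left_pos) / left_n
            + right_pos * (right_n - right_pos) / right_n
        ) * (2.0 / total)
    decrease = parent - weighted

    distinct = vals[1:] > vals[:-1]
    i = np.arange(1, n)[:, None]
    admissible = distinct & (i >= min_samples_leaf) & (total - i >= min_samples_leaf)
    decrease = np.where(admissible, decrease, -np.inf)

    # argmax over features first, then positions: the first flat maximum in
    # feature-major order realizes the lowest-feature / smallest-threshold tie-break
    flat = decrease.T.ravel()
    best = int(np.argmax(flat))
    best_dec = flat[best]
    if not np.isfinite(best_dec) or best_dec <= _EPS:
        return None
    f = best // (n - 1)
    pos = best % (n - 1) + 1
    lo = float(vals[pos - 1, f])
    hi = float(vals[pos, f])
    thr = lo + (hi - lo) / 2.0
    if not (lo <= thr < hi):  # guard against midpoint rounding onto hi
        thr = lo
    return f, thr, float(best_dec)


def find_best_split(
    X: np.ndarray, y: np.ndarray, config: TreeConfig | None = None
) -> tuple[int, float] | None:
    """Best (feature_index, threshold) for one node, or None."""
    config = config or TreeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X/y shape mismatch")
    if X.shape[0] < config.min_samples_split:
        return None
    sorted_idx = np.argsort(X, axis=0, kind="stable")
    res = _best_split_sorted(X, y, sorted_idx, config.min_samples_leaf)
    if res is None:
        return None
    f, thr, _ = res
    return f, thr


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: TreeConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> DecisionTreeModel:
    """Top-down induction to purity (or the configured limits)."""
    config = config or TreeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X must be 2-D with one label per row")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if len(feature_ids) != X.shape[1]:
        raise ValueError("feature_ids length mismatch")

    n, d = X.shape
    root_sorted = np.argsort(X, axis=0, kind="stable")

    def node_counts(rows: np.ndarray) -> tuple[int, int]:
        n1 = int(y[rows].sum())
        return (len(rows) - n1, n1)

    root = TreeNode(counts=node_counts(root_sorted[:, 0]))
    stack: list[tuple[TreeNode, np.ndarray, int]] = [(root, root_sorted, 0)]
    while stack:
        node, sorted_idx, depth = stack.pop()
        n_node = sorted_idx.shape[0]
        n0, n1 = node.counts
        pure = n0 == 0 or n1 == 0
        depth_capped = config.max_depth is not None and depth >= config.max_depth
        if pure or depth_capped or n_node < config.min_samples_split:
            continue
        res = _best_split_sorted(X, y, sorted_idx, config.min_samples_leaf)
        if res is None:
            continue
        f, thr, _ = res
        rows = sorted_idx[:, 0]
        go_left = np.zeros(n, dtype=bool)
        go_left[rows[X[rows, f] <= thr]] = True
        col_mask = go_left[sorted_idx]
        n_left = int(col_mask[:, 0].sum())
        left_sorted = sorted_idx.T[col_mask.T].reshape(d, n_left).T
        right_sorted = sorted_idx.T[~col_mask.T].reshape(d, n_node - n_left).T

        node.feature = f
        node.threshold = thr
        node.left = TreeNode(counts=node_counts(left_sorted[:, 0]))
        node.right = TreeNode(counts=node_counts(right_sorted[:, 0]))
        stack.append((node.left, left_sorted, depth + 1))
        stack.append((node.right, right_sorted, depth + 1))

    return DecisionTreeModel(
        root=root, feature_ids=list(feature_ids), class_totals=node_counts(np.arange(n))
    )


def predict_label(model: DecisionTreeModel, sample: np.ndarray) -> int:
    """Route one sample to its leaf (value <= threshold goes left)."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.n_features,):
        raise ValueError(
            f"sample has {sample.shape} values, model expects {model.n_features}"
        )
    node = model.root
    while not node.is_leaf:
        node = node.left if sample[node.feature] <= node.threshold else node.right
    return node.prediction


def predict(model: DecisionTreeModel, X: np.ndarray) -> np.ndarray:
    """Vectorized leaf routing for a samples x features matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError("X dimensionality does not match the model")
    out = np.empty(X.shape[0], dtype=int)
    idx = np.arange(X.shape[0])
    stack = [(model.root, idx)]
    while stack:
        node, rows = stack.pop()
        if len(rows) == 0:
            continue
        if node.is_leaf:
            out[rows] = node.prediction
            continue
        mask = X[rows, node.feature] <= node.threshold
        stack.append((node.left, rows[mask]))
        stack.append((node.right, rows[~mask]))
    return out
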