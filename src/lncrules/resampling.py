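"""SMOTE: grow the minority class to parity by linear interpolation.

Each synthetic sample is ``base + u * (neighbor - base)`` for a uniform
``u`` and a neighbor drawn from the base's k nearest minority neighbors
(Euclidean distance on raw feature values).  Bases are cycled in random
order across passes, so imbalances far larger than the minority size are
handled by reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SmoteConfig",
    "k_nearest_minority_neighbors",
    "synthesize_sample",
    "balance_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    target: str = "balance"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "balance":
            raise ValueError(f"unsupported target {self.target!r}")


def k_nearest_minority_neighbors(
    samples: np.ndarray, index: int, k: int
) -> np.ndarray:
    """Indices of the k nearest samples to ``samples[index]``, self excluded.

    Distance ties break toward the lower index; if fewer than k others
    exist, all of them are returned.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need at least two minority samples for neighbor search")
    if not (0 <= index < samples.shape[0]):
        raise IndexError(f"index {index} out of range")
    d = np.linalg.norm(samples - samples[index], axis=1)
    others = np.delete(np.arange(samples.shape[0]), index)
    order = others[np.argsort(d[others], kind="stable")]  # stable -> lower index on ties
    return order[: min(k, len(others))]


def synthesize_sample(
    base: np.ndarray, neighbor: np.ndarray, u: float
) -> np.ndarray:
    """Point on the segment from base to neighbor at fraction u."""
    base = np.asarray(base, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if base.shape != neighbor.shape:
        raise ValueError("base and neighbor dimensionality differ")
    return base + u * (neighbor - base)


def balance_dataset(
    values: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad the minority class with synthetic samples to the majority count.

    Returns ``(values_out, labels_out, synthetic)`` where ``synthetic`` is a
    boolean provenance flag (False for every original sample).  Original
    rows come first, unmodified.  Already-balanced input is returned as-is.
    """
    config = config or SmoteConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.ndim != 2 or values.shape[0] != labels.shape[0]:
        raise ValueError("values/labels shape mismatch")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balance_dataset requires exactly two classes")
    n_orig = values.shape[0]
    if counts[0] == counts[1]:
        return values, labels, np.zeros(n_orig, dtype=bool)

    minority_label = classes[np.argmin(counts)]
    minority_idx = np.flatnonzero(labels == minority_label)
    m = len(minority_idx)
    n_syn = int(counts.max() - counts.min())
    if m < 2:
        raise ValueError(
            "SMOTE needs at least two minority samples to interpolate between"
        )
    k = config.k_neighbors
    if k > m - 1:
        logger.warning("k_neighbors=%d capped at minority size - 1 = %d", k, m - 1)
        k = m - 1

    minority = values[minority_idx]
    # all-pairs kNN among the minority, ties toward the lower index
    dist = cdist(minority, minority)
    np.fill_diagonal(dist, np.inf)
    knn = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(config.seed)
    n_passes = -(-n_syn // m)
    base_order = np.concatenate([rng.permutation(m) for _ in range(n_passes)])[:n_syn]
    neighbor_pick = rng.integers(0, k, size=n_syn)
    u = rng.random(n_syn)

    bases = minority[base_order]
    neighbors = minority[knn[base_order, neighbor_pick]]
    synth = bases + u[:, None] * (neighbors - bases)

    values_out = np.vstack([values, synth])
    labels_out = np.concatenate([labels, np.full(n_syn, minority_label, dtype=int)])
    synthetic = np.concatenate([np.zeros(n_orig, dtype=bool), np.ones(n_syn, dtype=bool)])
    return values_out, labels_out, synthetic
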