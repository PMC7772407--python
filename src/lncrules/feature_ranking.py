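"""mRMR feature ranking on discretized enrichment scores.

Scores are discretized per feature into three codes (below mean - t*sd,
within, above mean + t*sd), mutual information is computed on the code
tables in bits, and features are ranked greedily by the MID criterion:
relevance to the label minus mean redundancy to the already-selected
features.  Ranking runs on the original (imbalanced) data — any resampling
happens strictly downstream of this step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .enrichment import FeatureMatrix

__all__ = [
    "DiscretizationPolicy",
    "RankedFeature",
    "RankedFeatureList",
    "discretize_feature",
    "discretize_matrix",
    "mutual_information",
    "mrmr_rank",
]


@dataclass(frozen=True)
class DiscretizationPolicy:
    """Three-code discretization at mean +/- t * sd (population sd)."""

    threshold_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")


@dataclass(frozen=True)
class RankedFeature:
    rank: int
    feature_id: str
    relevance: float
    redundancy: float
    score: float


@dataclass
class RankedFeatureList:
    entries: list[RankedFeature]

    def __post_init__(self) -> None:
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..F in order")
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature_ids in ranked list")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tfeature_id\trelevance\tredundancy\tscore\n")
            for e in self.entries:
                fh.write(
                    f"{e.rank}\t{e.feature_id}\t{e.relevance!r}\t"
                    f"{e.redundancy!r}\t{e.score!r}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedFeatureList":
        entries: list[RankedFeature] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["rank", "feature_id"]:
                raise ValueError(f"{path}: unexpected ranked-list header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                rank, fid, rel, red, score = line.split("\t")
                entries.append(
                    RankedFeature(int(rank), fid, float(rel), float(red), float(score))
                )
        return cls(entries)


def discretize_feature(
    values: np.ndarray, policy: DiscretizationPolicy | None = None
) -> np.ndarray:
    """Map a real vector to codes {-1, 0, +1} around mean +/- t*sd."""
    policy = policy or DiscretizationPolicy()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mean = values.mean()
    sd = values.std()  # population sd
    codes = np.zeros(values.shape, dtype=np.int8)
    if sd == 0:
        return codes
    t = policy.threshold_multiplier
    codes[values > mean + t * sd] = 1
    codes[values < mean - t * sd] = -1
    return codes


def discretize_matrix(
    values: np.ndarray, policy: DiscretizationPolicy | None = None
) -> np.ndarray:
    """Column-wise discretization of a samples x features matrix."""
    policy = policy or DiscretizationPolicy()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    t = policy.threshold_multiplier
    codes = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[values > mean + t * sd] = 1
        codes[values < mean - t * sd] = -1
    codes[:, sd == 0] = 0
    return codes


def _mi_from_joint(counts: np.ndarray) -> float:
    """MI in bits from a 2-D joint count table."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty joint table")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px * py)[nz])))


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Discrete mutual information in bits; symmetric and >= 0."""
    x = np.asarray(x_codes)
    y = np.asarray(y_codes)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("code vectors must be 1-D, equal length and non-empty")
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((len(xv), len(yv)), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return max(0.0, _mi_from_joint(counts))


def _mi_block(onehot_a: np.ndarray, onehot_all: np.ndarray, n_features: int) -> np.ndarray:
    """MI in bits between one coded vector and every feature column.

    ``onehot_a`` is (n, ka); ``onehot_all`` is (n, 3 * n_features) with the
    three-code one-hot blocks laid out feature-major.  Returns a length
    ``n_features`` vector.
    """
    n = onehot_a.shape[0]
    counts = onehot_a.T @ onehot_all  # (ka, 3F)
    ka = counts.shape[0]
    joint = counts.reshape(ka, n_features, 3).transpose(1, 0, 2) / n  # (F, ka, 3)
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    denom = px * py
    nz = joint > 0
    terms = np.zeros_like(joint)
    terms[nz] = joint[nz] * np.log2(joint[nz] / denom[nz])
    return np.maximum(0.0, terms.sum(axis=(1, 2)))


def mrmr_rank(
    matrix: FeatureMatrix, policy: DiscretizationPolicy | None = None
) -> RankedFeatureList:
    """Greedy MID ranking: argmax I(f; y) - mean_{s in selected} I(f; s).

    The first pick maximizes relevance alone.  Criterion ties break toward
    the smaller original column index, making the list deterministic.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    y = matrix.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; relevance undefined")
    F = matrix.n_features
    if F < 1:
        raise ValueError("need at least one feature")
    n = matrix.n_entities

    codes = discretize_matrix(matrix.values, policy) + 1  # {0,1,2}
    onehot = np.zeros((n, 3 * F), dtype=np.float64)
    cols = np.arange(F) * 3
    onehot[np.arange(n)[:, None], cols[None, :] + codes] = 1.0

    y01 = (y == classes.max()).astype(np.int8)
    y_onehot = np.zeros((n, 2), dtype=np.float64)
    y_onehot[np.arange(n), y01] = 1.0

    relevance = _mi_block(y_onehot, onehot, F)

    selected: list[int] = []
    red_sum = np.zeros(F)
    remaining = np.ones(F, dtype=bool)
    entries: list[RankedFeature] = []
    for rank in range(1, F + 1):
        if not selected:
            score = np.where(remaining, relevance, -np.inf)
            redundancy = np.zeros(F)
        else:
            last = selected[-1]
            block = onehot[:, 3 * last : 3 * last + 3]
            red_sum += _mi_block(block, onehot, F)
            redundancy = red_sum / len(selected)
            score = np.where(remaining, relevance - redundancy, -np.inf)
        pick = int(np.argmax(score))  # first max -> lowest column index on ties
        entries.append(
            RankedFeature(
                rank=rank,
                feature_id=matrix.feature_ids[pick],
                relevance=float(relevance[pick]),
                redundancy=float(redundancy[pick]),
                score=float(score[pick]),
            )
        )
        selected.append(pick)
        remaining[pick] = False
    return RankedFeatureList(entries)
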