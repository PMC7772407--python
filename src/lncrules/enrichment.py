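"""Hypergeometric enrichment-score encoding of entities from their gene sets.

Each entity (e.g. an lncRNA) is described by a set of co-expressed genes
``G(x)``.  For every annotation term (a named gene set, GO-like or
KEGG-like) the entity receives a score

    S = -log10( sum_{l=m}^{min(n, M)} C(M, l) C(N-M, n-l) / C(N, n) )

where ``N`` is the gene-universe size, ``M`` the in-universe term size,
``n = |G(x)|`` (restricted to the universe) and ``m`` the overlap.  The sum
is the upper tail of the hypergeometric distribution; large scores mean the
overlap is unlikely under random draws.  All computation is done in natural
log space (log-gamma factorials plus log-sum-exp) so very large universes
neither overflow nor underflow.

This module also owns the plain-text readers/writers for the exchange
formats: GMT term databases, entity/gene pair TSVs, label TSVs and the
feature-matrix TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneUniverse",
    "TermAnnotation",
    "AnnotationDatabase",
    "CoexpressionProfile",
    "EnrichmentQuery",
    "FeatureMatrix",
    "hypergeometric_tail_log10",
    "enrichment_score",
    "encode_profiles",
    "read_gmt",
    "write_gmt",
    "read_pairs",
    "write_pairs",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneUniverse:
    """The reference set of genes; all counts are taken relative to it."""

    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValueError("gene universe must contain at least one gene")

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        return cls(frozenset(genes))

    @property
    def N(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class TermAnnotation:
    """A named gene set with a namespace tag ("GO" or "KEGG")."""

    term_id: str
    namespace: str
    gene_set: frozenset[str]
    description: str = ""

    def in_universe_size(self, universe: GeneUniverse) -> int:
        return len(self.gene_set & universe.gene_ids)


@dataclass
class AnnotationDatabase:
    """Ordered term collection; the order defines the feature order.

    GO-namespace terms come first, then KEGG, matching the fixed layout of
    the encoded feature vector.
    """

    terms: list[TermAnnotation]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term_ids in annotation database")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.gene_set
        return frozenset(out)


@dataclass(frozen=True)
class CoexpressionProfile:
    """An entity and its co-expressed gene set G(x)."""

    entity_id: str
    gene_set: frozenset[str]

    def in_universe_size(self, universe: GeneUniverse) -> int:
        return len(self.gene_set & universe.gene_ids)


@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts (N, M, n, m) for a single hypergeometric tail evaluation."""

    N: int
    M: int
    n: int
    m: int

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError(f"universe size N must be >= 1, got {self.N}")
        for name in ("M", "n", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.M > self.N:
            raise ValueError(f"M={self.M} exceeds N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds N={self.N}")
        if self.m > min(self.M, self.n):
            raise ValueError(
                f"m={self.m} exceeds min(M, n)={min(self.M, self.n)}"
            )


@dataclass
class FeatureMatrix:
    """Entities x terms score matrix with optional binary labels."""

    entity_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.entity_ids)} entities x {len(self.feature_ids)} features"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.entity_ids),):
                raise ValueError("labels length does not match entity count")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("entity_id\t" + "\t".join(self.feature_ids) + "\n")
            for i, eid in enumerate(self.entity_ids):
                row = "\t".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{eid}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "entity_id":
                raise ValueError(f"{path}: expected 'entity_id' as first column")
            feature_ids = header[1:]
            entity_ids: list[str] = []
            rows: list[list[float]] = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                entity_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        values = np.array(rows, dtype=float) if rows else np.zeros((0, len(feature_ids)))
        return cls(entity_ids, feature_ids, values)


# ---------------------------------------------------------------------------
# Core scoring
# ---------------------------------------------------------------------------


def _log_comb(a, b):
    """log C(a, b), elementwise; -inf where b < 0 or b > a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (b >= 0) & (b <= a)
    safe_b = np.where(ok, b, 0.0)
    out = gammaln(a + 1.0) - gammaln(safe_b + 1.0) - gammaln(a - safe_b + 1.0)
    return np.where(ok, out, -np.inf)


def hypergeometric_tail_log10(q: EnrichmentQuery) -> float:
    """-log10 of the hypergeometric upper-tail probability P(X >= m).

    Evaluated term by term in natural-log space and combined with
    log-sum-exp; exact to floating precision even for N in the tens of
    thousands.  Always >= 0 (the tail is a probability).
    """
    q.validate()
    if q.m == 0:
        return 0.0  # tail from zero sums to exactly 1
    upper = min(q.n, q.M)
    l = np.arange(q.m, upper + 1)
    log_terms = (
        _log_comb(q.M, l)
        + _log_comb(q.N - q.M, q.n - l)
        - _log_comb(q.N, q.n)
    )
    log_p = logsumexp(log_terms)
    return max(0.0, -log_p / _LN10)


def enrichment_score(
    universe: GeneUniverse,
    term: TermAnnotation,
    profile: CoexpressionProfile,
) -> float:
    """Score one (entity, term) pair; genes outside the universe are ignored."""
    term_genes = term.gene_set & universe.gene_ids
    profile_genes = profile.gene_set & universe.gene_ids
    n = len(profile_genes)
    if n == 0:
        logger.warning(
            "entity %s has no in-universe genes; score defaults to 0",
            profile.entity_id,
        )
        return 0.0
    q = EnrichmentQuery(
        N=universe.N,
        M=len(term_genes),
        n=n,
        m=len(profile_genes & term_genes),
    )
    return hypergeometric_tail_log10(q)


def _tail_log10_column(N: int, M: int, n_vec: np.ndarray, m_vec: np.ndarray) -> np.ndarray:
    """Vectorized tail scores for one term against many profiles.

    Flattens the ragged per-cell summations l = m..min(n, M) into one array
    and reduces per segment (max + log-sum-exp), which keeps the encoding of
    a full matrix at interactive speed.
    """
    scores = np.zeros(len(n_vec), dtype=float)
    upper = np.minimum(n_vec, M)
    active = (m_vec >= 1) & (m_vec <= upper)
    if not np.any(active):
        return scores
    m_a = m_vec[active]
    up_a = upper[active]
    n_a = n_vec[active]
    lengths = up_a - m_a + 1
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    total = int(lengths.sum())
    # l values: for each segment, m..upper
    l = np.arange(total) - np.repeat(starts, lengths) + np.repeat(m_a, lengths)
    n_rep = np.repeat(n_a, lengths)
    log_terms = (
        _log_comb(M, l)
        + _log_comb(N - M, n_rep - l)
        - _log_comb(N, n_rep)
    )
    seg_max = np.maximum.reduceat(log_terms, starts)
    seg_max = np.where(np.isfinite(seg_max), seg_max, 0.0)
    shifted = np.exp(log_terms - np.repeat(seg_max, lengths))
    seg_sum = np.add.reduceat(shifted, starts)
    log_p = seg_max + np.log(seg_sum)
    scores[active] = np.maximum(0.0, -log_p / _LN10)
    return scores


def encode_profiles(
    universe: GeneUniverse,
    db: AnnotationDatabase,
    profiles: Sequence[CoexpressionProfile],
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Encode every profile against every term into a FeatureMatrix.

    Cell (i, j) equals ``enrichment_score(universe, db.terms[j], profiles[i])``;
    columns follow the database order.
    """
    if len(db) == 0:
        raise ValueError("annotation database is empty")
    if len(profiles) == 0:
        raise ValueError("no profiles to encode")
    entity_ids = [p.entity_id for p in profiles]
    if len(set(entity_ids)) != len(entity_ids):
        raise ValueError("duplicate entity_ids in profiles")

    gene_index = {g: i for i, g in enumerate(sorted(universe.gene_ids))}
    N = universe.N

    P = np.zeros((len(profiles), N), dtype=np.float64)
    for i, p in enumerate(profiles):
        idx = [gene_index[g] for g in p.gene_set if g in gene_index]
        P[i, idx] = 1.0
    T = np.zeros((len(db), N), dtype=np.float64)
    for j, t in enumerate(db):
        idx = [gene_index[g] for g in t.gene_set if g in gene_index]
        T[j, idx] = 1.0

    n_vec = P.sum(axis=1).astype(np.int64)
    M_vec = T.sum(axis=1).astype(np.int64)
    overlap = np.rint(P @ T.T).astype(np.int64)  # (entities, terms)

    if np.any(n_vec == 0):
        for i in np.flatnonzero(n_vec == 0):
            logger.warning(
                "entity %s has no in-universe genes; scores default to 0",
                profiles[i].entity_id,
            )

    values = np.zeros((len(profiles), len(db)), dtype=float)
    for j in range(len(db)):
        values[:, j] = _tail_log10_column(N, int(M_vec[j]), n_vec, overlap[:, j])

    return FeatureMatrix(entity_ids, db.term_ids, values, labels=labels)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> AnnotationDatabase:
    """Read a GMT file (term_id, description, then gene ids, tab-separated).

    The namespace is inferred from the term id prefix: ids starting with
    "KEGG" are tagged KEGG, everything else GO.
    """
    terms: list[TermAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line: {line!r}")
            term_id, description = parts[0], parts[1]
            namespace = "KEGG" if term_id.upper().startswith("KEGG") else "GO"
            terms.append(
                TermAnnotation(term_id, namespace, frozenset(parts[2:]), description)
            )
    return AnnotationDatabase(terms)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in db:
            genes = "\t".join(sorted(t.gene_set))
            fh.write(f"{t.term_id}\t{t.description}\t{genes}\n")


def read_pairs(path: str | Path) -> list[CoexpressionProfile]:
    """Read entity/gene pair TSV (header 'entity_id\\tgene_id').

    Entity order follows first appearance in the file.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["entity_id", "gene_id"]:
            raise ValueError(f"{path}: expected header 'entity_id\\tgene_id'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            entity_id, gene_id = line.split("\t")[:2]
            sets.setdefault(entity_id, set()).add(gene_id)
    return [CoexpressionProfile(eid, frozenset(g)) for eid, g in sets.items()]


def write_pairs(profiles: Sequence[CoexpressionProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tgene_id\n")
        for p in profiles:
            for g in sorted(p.gene_set):
                fh.write(f"{p.entity_id}\t{g}\n")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a label TSV (header 'entity_id\\tlabel'); returns (ids, 0/1 array)."""
    ids: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["entity_id", "label"]:
            raise ValueError(f"{path}: expected header 'entity_id\\tlabel'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            eid, lab = line.split("\t")[:2]
            ids.append(eid)
            labels.append(int(lab))
    return ids, np.asarray(labels, dtype=int)


def write_labels(entity_ids: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tlabel\n")
        for eid, lab in zip(entity_ids, labels):
            fh.write(f"{eid}\t{int(lab)}\n")
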