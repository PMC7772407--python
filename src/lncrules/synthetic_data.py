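"""Synthetic annotation databases, co-expression profiles and labels.

Generates the three pipeline inputs with a planted class signal: a handful
of "discriminative" terms whose gene union positives preferentially sample
their co-expressed genes from.  Class imbalance is configurable up to the
~1:260 regime of real rare-positive screens.

The random stream is consumed in a fixed, documented order — terms, then
the planted truth, then entities — so identical (config, seed) pairs yield
byte-identical fixtures on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import (
    AnnotationDatabase,
    CoexpressionProfile,
    TermAnnotation,
    write_gmt,
    write_labels,
    write_pairs,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_annotation_db",
    "plant_truth",
    "generate_coexpression_profiles",
    "generate_dataset",
    "write_fixture",
]


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_go_terms: int = 288
    n_kegg_terms: int = 12
    term_size_range: tuple[int, int] = (10, 300)
    n_positive: int = 57
    n_negative: int = 1000
    n_discriminative_terms: int = 10
    discriminative_size_range: tuple[int, int] = (15, 45)
    signal_fraction: float = 0.3
    coexpr_size_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_go_terms", "n_kegg_terms", "n_positive", "n_negative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_discriminative_terms < 0:
            raise ValueError("n_discriminative_terms must be >= 0")
        if self.n_discriminative_terms > self.n_go_terms + self.n_kegg_terms:
            raise ValueError("n_discriminative_terms exceeds total term count")
        for name in ("term_size_range", "coexpr_size_range", "discriminative_size_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty positive range")
        if self.term_size_range[1] > self.n_genes:
            raise ValueError("term_size_range upper bound exceeds n_genes")
        if self.coexpr_size_range[1] > self.n_genes:
            raise ValueError("coexpr_size_range upper bound exceeds n_genes")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Which terms carry the planted signal, and the entity labels."""

    discriminative_term_ids: list[str]
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_annotation_db(
    config: SyntheticConfig, rng: np.random.Generator
) -> AnnotationDatabase:
    """Random term database: GO terms first, then KEGG, sizes uniform in range."""
    config.validate()
    genes = np.array(_gene_names(config.n_genes))
    lo, hi = config.term_size_range
    terms: list[TermAnnotation] = []
    specs = [("GO", config.n_go_terms), ("KEGG", config.n_kegg_terms)]
    for namespace, count in specs:
        for i in range(1, count + 1):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(genes, size=size, replace=False)
            if namespace == "GO":
                tid = f"GO:{i:07d}"
            else:
                tid = f"KEGG:{i:05d}"
            terms.append(
                TermAnnotation(tid, namespace, frozenset(members.tolist()),
                               f"synthetic {namespace} term {i}")
            )
    return AnnotationDatabase(terms)


def plant_truth(
    config: SyntheticConfig, db: AnnotationDatabase, rng: np.random.Generator
) -> SyntheticTruth:
    """Pick the discriminative terms uniformly among moderately sized ones.

    Eligibility is limited to terms whose size falls in
    ``discriminative_size_range``: very large planted terms inflate the
    signal-gene union until the per-term overlap of a positive is barely
    above the background rate, which would make the planted signal
    undetectable by construction rather than by failure of the method.
    """
    lo, hi = config.discriminative_size_range
    ids = np.array([t.term_id for t in db if lo <= len(t.gene_set) <= hi])
    if len(ids) < config.n_discriminative_terms:
        raise ValueError(
            f"only {len(ids)} terms have sizes in {config.discriminative_size_range}; "
            f"cannot plant {config.n_discriminative_terms} discriminative terms"
        )
    chosen = rng.choice(ids, size=config.n_discriminative_terms, replace=False)
    return SyntheticTruth(discriminative_term_ids=chosen.tolist())


def generate_coexpression_profiles(
    config: SyntheticConfig,
    db: AnnotationDatabase,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[list[CoexpressionProfile], np.ndarray]:
    """Entity gene sets plus 0/1 labels (positives first).

    Negatives draw uniformly from the gene universe.  Positives draw a
    ``signal_fraction`` share of their genes from the union of the
    discriminative terms' gene sets (with replacement, de-duplicated), then
    top up from the rest of the universe to hit the drawn set size exactly.
    """
    config.validate()
    db_ids = set(db.term_ids)
    for tid in truth.discriminative_term_ids:
        if tid not in db_ids:
            raise ValueError(f"discriminative term {tid} not in database")
    term_by_id = {t.term_id: t for t in db}
    signal_union = sorted(
        set().union(*(term_by_id[t].gene_set for t in truth.discriminative_term_ids))
        if truth.discriminative_term_ids
        else set()
    )
    if config.signal_fraction > 0 and not signal_union:
        raise ValueError("signal_fraction > 0 requires a non-empty discriminative union")

    universe = np.array(_gene_names(config.n_genes))
    signal_pool = np.array(signal_union)
    lo, hi = config.coexpr_size_range

    profiles: list[CoexpressionProfile] = []
    labels = np.concatenate(
        [np.ones(config.n_positive, dtype=int), np.zeros(config.n_negative, dtype=int)]
    )
    n_total = config.n_positive + config.n_negative
    width = max(4, len(str(n_total)))
    for i in range(n_total):
        eid = f"lnc{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if labels[i] == 1 and config.signal_fraction > 0:
            n_signal = int(round(config.signal_fraction * size))
            picked = set(rng.choice(signal_pool, size=n_signal, replace=True).tolist())
            # top up from the remaining universe to hit the drawn size exactly
            need = size - len(picked)
            if need > 0:
                rest = np.array([g for g in universe if g not in picked])
                picked |= set(rng.choice(rest, size=need, replace=False).tolist())
            genes = frozenset(picked)
        else:
            genes = frozenset(rng.choice(universe, size=size, replace=False).tolist())
        profiles.append(CoexpressionProfile(eid, genes))
    truth.labels = labels
    return profiles, labels


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AnnotationDatabase, SyntheticTruth, list[CoexpressionProfile], np.ndarray]:
    """Full fixture from one seeded stream: terms, then truth, then entities."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    db = generate_annotation_db(config, rng)
    truth = plant_truth(config, db, rng)
    profiles, labels = generate_coexpression_profiles(config, db, truth, rng)
    return db, truth, profiles, labels


def write_fixture(
    outdir: str | Path,
    db: AnnotationDatabase,
    profiles: Sequence[CoexpressionProfile],
    labels: np.ndarray,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write the GMT / pairs / labels files (plus planted truth if given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": outdir / "annotations.gmt",
        "pairs": outdir / "coexpression.tsv",
        "labels": outdir / "labels.tsv",
    }
    write_gmt(db, paths["gmt"])
    write_pairs(profiles, paths["pairs"])
    write_labels([p.entity_id for p in profiles], labels, paths["labels"])
    if truth is not None:
        paths["truth"] = outdir / "planted_terms.txt"
        with open(paths["truth"], "w") as fh:
            for tid in truth.discriminative_term_ids:
                fh.write(tid + "\n")
    return paths
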