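import numpy as np
import pytest

from lncrules.enrichment import (
    AnnotationDatabase,
    CoexpressionProfile,
    GeneUniverse,
    TermAnnotation,
    encode_profiles,
)
from lncrules.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_universe():
    """10 genes, hand-enumerable."""
    return GeneUniverse.from_iterable(f"g{i}" for i in range(10))


@pytest.fixture(scope="session")
def tiny_db():
    """4 terms over the 10-gene universe (3 GO + 1 KEGG)."""
    return AnnotationDatabase(
        [
            TermAnnotation("GO:1", "GO", frozenset({"g0", "g1", "g2", "g3"})),
            TermAnnotation("GO:2", "GO", frozenset({"g4", "g5"})),
            TermAnnotation("GO:3", "GO", frozenset({"g0", "g5", "g9"})),
            TermAnnotation("KEGG:1", "KEGG", frozenset({"g6", "g7", "g8"})),
        ]
    )


@pytest.fixture(scope="session")
def tiny_profiles():
    """3 entities over the 10-gene universe."""
    return [
        CoexpressionProfile("e1", frozenset({"g0", "g1", "g2"})),
        CoexpressionProfile("e2", frozenset({"g4", "g5", "g6", "g7"})),
        CoexpressionProfile("e3", frozenset({"g9"})),
    ]


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-signal dataset at seed 1, encoded once per session."""
    cfg = SyntheticConfig(seed=1)
    db, truth, profiles, labels = generate_dataset(cfg)
    universe = GeneUniverse.from_iterable(
        set().union(*(p.gene_set for p in profiles)) | set(db.all_genes())
    )
    matrix = encode_profiles(universe, db, profiles, labels=labels)
    return {
        "config": cfg,
        "db": db,
        "truth": truth,
        "profiles": profiles,
        "labels": labels,
        "universe": universe,
        "matrix": matrix,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
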