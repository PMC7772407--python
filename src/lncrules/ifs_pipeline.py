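"""Incremental feature selection over the mRMR list, and the full pipeline.

IFS evaluates nested prefixes of the ranked feature list (sizes step,
2*step, ..., F) with cross-validated CART, records one metrics report per
size, and selects both the MCC optimum (ties toward fewer features) and a
trade-off subset: the smallest size whose MCC is within ``tradeoff_delta``
of the maximum.  The final interpretable model is a tree refit on all
samples restricted to the chosen subset, exported as decision rules.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cart import DecisionTreeModel, TreeConfig, grow_tree
from .enrichment import (
    FeatureMatrix,
    GeneUniverse,
    encode_profiles,
    read_gmt,
    read_labels,
    read_pairs,
)
from .evaluation import MetricsReport, cross_validate
from .feature_ranking import DiscretizationPolicy, RankedFeatureList, mrmr_rank
from .resampling import SmoteConfig, balance_dataset
from .rules import RuleSet, extract_rules, summarize_rules

__all__ = [
    "IFSPoint",
    "IFSCurve",
    "PipelineConfig",
    "build_subset_sizes",
    "run_ifs",
    "select_tradeoff",
    "train_final_rule_model",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IFSPoint:
    n_features: int
    metrics: MetricsReport


@dataclass
class IFSCurve:
    points: list[IFSPoint]
    step: int

    def __post_init__(self) -> None:
        sizes = [p.n_features for p in self.points]
        if sizes != sorted(set(sizes)) or (sizes and sizes[0] < 1):
            raise ValueError("curve sizes must be strictly increasing and >= 1")

    @property
    def optimum(self) -> IFSPoint:
        """Maximal-MCC point; ties resolve to the smallest subset."""
        best = self.points[0]
        for p in self.points[1:]:
            if p.metrics.MCC > best.metrics.MCC:
                best = p
        return best

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n_features\tSN\tSP\tACC\tMCC\tPrecision\tF1\n")
            for p in self.points:
                m = p.metrics
                fh.write(
                    f"{p.n_features}\t{m.SN!r}\t{m.SP!r}\t{m.ACC!r}\t"
                    f"{m.MCC!r}\t{m.Precision!r}\t{m.F1!r}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, step: int = 1) -> "IFSCurve":
        points: list[IFSPoint] = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                vals = line.split("\t")
                points.append(
                    IFSPoint(
                        int(vals[0]),
                        MetricsReport(*(float(v) for v in vals[1:7])),
                    )
                )
        return cls(points=points, step=step)


@dataclass
class PipelineConfig:
    gmt_path: str | Path
    pairs_path: str | Path
    labels_path: str | Path
    universe_path: str | Path | None = None  # None -> infer from inputs
    step: int = 10
    k_folds: int = 10
    smote_mode: str = "train_only"
    smote_k: int = 5
    tradeoff_delta: float = 0.025
    final_smote: bool = True
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    fold_seed: int = 0
    smote_seed: int = 0

    def validate(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.tradeoff_delta < 0:
            raise ValueError("tradeoff_delta must be >= 0")


def build_subset_sizes(n_features: int, step: int) -> list[int]:
    """step, 2*step, ... up to n_features, which is always included."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    sizes = list(range(step, n_features + 1, step))
    if not sizes or sizes[-1] != n_features:
        sizes.append(n_features)
    return sizes


def run_ifs(
    matrix: FeatureMatrix,
    ranked: RankedFeatureList,
    step: int = 10,
    tree_config: TreeConfig | None = None,
    smote_mode: str = "train_only",
    k_folds: int = 10,
    fold_seed: int = 0,
    smote_config: SmoteConfig | None = None,
) -> IFSCurve:
    """Cross-validate CART on every ranked-prefix subset."""
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    col = {fid: j for j, fid in enumerate(matrix.feature_ids)}
    try:
        order = [col[fid] for fid in ranked.feature_ids]
    except KeyError as e:
        raise ValueError(f"ranked feature {e} not present in matrix") from e
    points: list[IFSPoint] = []
    for size in build_subset_sizes(len(order), step):
        metrics = cross_validate(
            matrix.values,
            matrix.labels,
            feature_indices=order[:size],
            tree_config=tree_config,
            smote_mode=smote_mode,
            k=k_folds,
            fold_seed=fold_seed,
            smote_config=smote_config,
        )
        points.append(IFSPoint(size, metrics))
        logger.info("IFS size=%d MCC=%.4f", size, metrics.MCC)
    return IFSCurve(points=points, step=step)


def select_tradeoff(curve: IFSCurve, delta: float = 0.025) -> int:
    """Smallest subset size with MCC within delta of the curve maximum."""
    if not curve.points:
        raise ValueError("empty IFS curve")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    max_mcc = max(p.metrics.MCC for p in curve.points)
    for p in curve.points:
        if p.metrics.MCC >= max_mcc - delta:
            return p.n_features
    raise AssertionError("unreachable: the maximum always qualifies")


def train_final_rule_model(
    matrix: FeatureMatrix,
    ranked: RankedFeatureList,
    n_features: int,
    smote: bool = True,
    tree_config: TreeConfig | None = None,
    smote_config: SmoteConfig | None = None,
) -> tuple[DecisionTreeModel, RuleSet, str]:
    """Refit on all samples with the chosen subset; return tree, rules, report."""
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    if n_features > matrix.n_features:
        raise ValueError("requested subset exceeds the feature count")
    col = {fid: j for j, fid in enumerate(matrix.feature_ids)}
    chosen = ranked.top(n_features)
    idx = [col[fid] for fid in chosen]
    X = matrix.values[:, idx]
    y = matrix.labels
    if smote:
        X, y, _ = balance_dataset(X, y, smote_config or SmoteConfig())
    model = grow_tree(X, y, tree_config, feature_ids=chosen)
    ruleset = extract_rules(model)
    report = summarize_rules(ruleset)
    return model, ruleset, report


def _plot_curve(curve: IFSCurve, tradeoff_size: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = [p.n_features for p in curve.points]
    mccs = [p.metrics.MCC for p in curve.points]
    opt = curve.optimum
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(sizes, mccs, "-o", ms=3, lw=1)
    ax.axvline(opt.n_features, color="tab:green", ls="--", lw=1,
               label=f"optimum ({opt.n_features}, MCC={opt.metrics.MCC:.3f})")
    ax.axvline(tradeoff_size, color="tab:orange", ls=":", lw=1,
               label=f"trade-off ({tradeoff_size})")
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("MCC (pooled 10-fold CV)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """encode -> rank -> IFS -> select -> final rules; writes all artifacts."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("load inputs")
        db = read_gmt(config.gmt_path)
        profiles = read_pairs(config.pairs_path)
        label_ids, labels = read_labels(config.labels_path)
        by_id = {p.entity_id: p for p in profiles}
        if set(label_ids) != set(by_id):
            raise ValueError("entity ids in labels and pairs files differ")
        profiles = [by_id[eid] for eid in label_ids]
        if config.universe_path is not None:
            genes = Path(config.universe_path).read_text().split()
            universe = GeneUniverse.from_iterable(genes)
        else:
            universe = GeneUniverse.from_iterable(
                set().union(*(p.gene_set for p in profiles)) | set(db.all_genes())
            )
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'load inputs' failed: {e}") from e

    try:
        stage("encode")
        matrix = encode_profiles(universe, db, profiles, labels=labels)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'encode' failed: {e}") from e

    try:
        stage("rank")
        ranked = mrmr_rank(matrix, DiscretizationPolicy())
        ranked.to_tsv(outdir / "ranked_features.tsv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'rank' failed: {e}") from e

    smote_config = SmoteConfig(k_neighbors=config.smote_k, seed=config.smote_seed)
    try:
        stage("ifs")
        curve = run_ifs(
            matrix,
            ranked,
            step=config.step,
            tree_config=config.tree_config,
            smote_mode=config.smote_mode,
            k_folds=config.k_folds,
            fold_seed=config.fold_seed,
            smote_config=smote_config,
        )
        curve.to_tsv(outdir / "ifs_curve.tsv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'ifs' failed: {e}") from e

    try:
        stage("select")
        optimum = curve.optimum
        tradeoff_size = select_tradeoff(curve, config.tradeoff_delta)
        _plot_curve(curve, tradeoff_size, outdir / "ifs_curve.png")
        optimum.metrics.to_json(outdir / "optimum_metrics.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'select' failed: {e}") from e

    try:
        stage("final rules")
        model, ruleset, report = train_final_rule_model(
            matrix,
            ranked,
            tradeoff_size,
            smote=config.final_smote,
            tree_config=config.tree_config,
            smote_config=smote_config,
        )
        model.to_json(outdir / "final_tree.json")
        ruleset.to_json(outdir / "rules.json")
        (outdir / "rules.txt").write_text(report)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'final rules' failed: {e}") from e

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "inputs": {
            "gmt": str(config.gmt_path),
            "pairs": str(config.pairs_path),
            "labels": str(config.labels_path),
            "universe": str(config.universe_path) if config.universe_path else "infer",
        },
        "parameters": {
            "step": config.step,
            "k_folds": config.k_folds,
            "smote_mode": config.smote_mode,
            "smote_k": config.smote_k,
            "tradeoff_delta": config.tradeoff_delta,
            "final_smote": config.final_smote,
            "max_depth": config.tree_config.max_depth,
            "min_samples_split": config.tree_config.min_samples_split,
            "min_samples_leaf": config.tree_config.min_samples_leaf,
        },
        "seeds": {"fold": config.fold_seed, "smote": config.smote_seed},
        "n_entities": matrix.n_entities,
        "n_features": matrix.n_features,
        "optimum": {"n_features": optimum.n_features, "MCC": optimum.metrics.MCC},
        "tradeoff": {
            "n_features": tradeoff_size,
            "MCC": next(
                p.metrics.MCC for p in curve.points if p.n_features == tradeoff_size
            ),
        },
        "n_rules": len(ruleset),
        "n_identifying_rules": ruleset.n_positive_rules,
        "n_excluding_rules": ruleset.n_negative_rules,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
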