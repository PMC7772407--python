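import numpy as np
import pytest

from lncrules.enrichment import FeatureMatrix
from lncrules.evaluation import MetricsReport
from lncrules.feature_ranking import mrmr_rank
from lncrules.ifs_pipeline import (
    IFSCurve,
    IFSPoint,
    PipelineConfig,
    build_subset_sizes,
    run_ifs,
    run_pipeline,
    select_tradeoff,
    train_final_rule_model,
)
from lncrules.rules import apply_rules
from lncrules.synthetic_data import SyntheticConfig, generate_dataset, write_fixture


def metrics_with_mcc(mcc):
    return MetricsReport(SN=0.5, SP=0.5, ACC=0.5, MCC=mcc, Precision=0.5, F1=0.5)


def curve_from(pairs, step=10):
    return IFSCurve(
        points=[IFSPoint(n, metrics_with_mcc(m)) for n, m in pairs], step=step
    )


class TestSubsetSizes:
    def test_step_ten_with_remainder(self):
        assert build_subset_sizes(25, 10) == [10, 20, 25]

    def test_step_one_base_definition(self):
        assert build_subset_sizes(3, 1) == [1, 2, 3]

    def test_paper_scale_count(self):
        assert len(build_subset_sizes(19090, 10)) == 1909

    def test_exact_multiple_no_duplicate(self):
        assert build_subset_sizes(30, 10) == [10, 20, 30]

    def test_small_f(self):
        assert build_subset_sizes(4, 10) == [4]

    def test_invalid(self):
        with pytest.raises(ValueError):
            build_subset_sizes(0, 10)
        with pytest.raises(ValueError):
            build_subset_sizes(10, 0)


class TestOptimumAndTradeoff:
    def test_tie_prefers_fewer_features(self):
        curve = curve_from([(10, 0.2), (20, 0.5), (30, 0.5)])
        assert curve.optimum.n_features == 20

    def test_single_point_is_optimum(self):
        curve = curve_from([(7, 0.1)])
        assert curve.optimum.n_features == 7

    def test_tradeoff_delta_zero_is_optimum(self):
        curve = curve_from([(10, 0.2), (20, 0.5), (30, 0.4)])
        assert select_tradeoff(curve, 0.0) == 20

    def test_tradeoff_reported_pair(self):
        # echoes the in-range pair: 0.415 - 0.393 = 0.022 <= 0.025
        curve = curve_from([(10, 0.30), (20, 0.393), (30, 0.415)])
        assert select_tradeoff(curve, 0.025) == 20

    def test_tradeoff_large_delta_smallest_size(self):
        curve = curve_from([(10, 0.30), (20, 0.393), (30, 0.415)])
        assert select_tradeoff(curve, 1.0) == 10

    def test_curve_sizes_must_increase(self):
        with pytest.raises(ValueError):
            curve_from([(20, 0.1), (10, 0.2)])


def small_planted_fixture(seed=11):
    cfg = SyntheticConfig(
        n_genes=400,
        n_go_terms=28,
        n_kegg_terms=2,
        term_size_range=(5, 60),
        n_positive=15,
        n_negative=60,
        n_discriminative_terms=3,
        discriminative_size_range=(10, 40),
        coexpr_size_range=(15, 40),
        signal_fraction=0.5,
        seed=seed,
    )
    from lncrules.enrichment import GeneUniverse, encode_profiles

    db, truth, profiles, labels = generate_dataset(cfg)
    universe = GeneUniverse.from_iterable(
        set().union(*(p.gene_set for p in profiles)) | set(db.all_genes())
    )
    matrix = encode_profiles(universe, db, profiles, labels=labels)
    return cfg, db, truth, matrix


class TestRunIfs:
    def test_curve_structure_and_nesting(self):
        _, _, _, matrix = small_planted_fixture()
        ranked = mrmr_rank(matrix)
        curve = run_ifs(matrix, ranked, step=10, k_folds=5, fold_seed=0)
        sizes = [p.n_features for p in curve.points]
        assert sizes == build_subset_sizes(matrix.n_features, 10)
        assert curve.optimum.metrics.MCC == max(p.metrics.MCC for p in curve.points)

    def test_deterministic(self):
        _, _, _, matrix = small_planted_fixture()
        ranked = mrmr_rank(matrix)
        a = run_ifs(matrix, ranked, step=15, k_folds=5, fold_seed=2)
        b = run_ifs(matrix, ranked, step=15, k_folds=5, fold_seed=2)
        assert [p.metrics for p in a.points] == [p.metrics for p in b.points]

    def test_ranked_must_cover_matrix(self):
        _, _, _, matrix = small_planted_fixture()
        other = FeatureMatrix(
            matrix.entity_ids, [f"x{j}" for j in range(3)],
            matrix.values[:, :3], labels=matrix.labels,
        )
        ranked = mrmr_rank(other)
        with pytest.raises(ValueError, match="not present"):
            run_ifs(matrix, ranked, step=10, k_folds=5)

    def test_curve_tsv_round_trip(self, tmp_path):
        curve = curve_from([(10, 0.2), (20, 0.5)])
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        back = IFSCurve.from_tsv(path, step=10)
        assert [p.n_features for p in back.points] == [10, 20]
        assert back.points[1].metrics == curve.points[1].metrics


class TestFinalModel:
    def test_separable_training_accuracy(self):
        _, _, _, matrix = small_planted_fixture()
        ranked = mrmr_rank(matrix)
        model, ruleset, report = train_final_rule_model(
            matrix, ranked, matrix.n_features, smote=False
        )
        from lncrules.cart import predict

        cols = [matrix.feature_ids.index(f) for f in model.feature_ids]
        acc = (predict(model, matrix.values[:, cols]) == matrix.labels).mean()
        assert acc == 1.0  # distinct rows, unlimited depth

    def test_rule_tree_equivalence_both_smote_settings(self):
        _, _, _, matrix = small_planted_fixture()
        ranked = mrmr_rank(matrix)
        rng = np.random.default_rng(0)
        for smote in (False, True):
            model, ruleset, _ = train_final_rule_model(matrix, ranked, 10, smote=smote)
            from lncrules.cart import predict_label

            cols = [matrix.feature_ids.index(f) for f in ranked.top(10)]
            probes = rng.normal(
                loc=matrix.values[:, cols].mean(),
                scale=matrix.values[:, cols].std() + 1.0,
                size=(200, 10),
            )
            for s in probes:
                label, _ = apply_rules(ruleset, s)
                assert label == predict_label(model, s)

    def test_oversized_subset_rejected(self):
        _, _, _, matrix = small_planted_fixture()
        ranked = mrmr_rank(matrix)
        with pytest.raises(ValueError):
            train_final_rule_model(matrix, ranked, matrix.n_features + 1)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = SyntheticConfig(
        n_genes=400, n_go_terms=28, n_kegg_terms=2, term_size_range=(5, 60),
        n_positive=15, n_negative=60, n_discriminative_terms=3,
        discriminative_size_range=(10, 40), coexpr_size_range=(15, 40),
        signal_fraction=0.5, seed=11,
    )
    db, truth, profiles, labels = generate_dataset(cfg)
    return write_fixture(outdir, db, profiles, labels, truth)


class TestRunPipeline:
    def _config(self, paths, **kw):
        defaults = dict(
            gmt_path=paths["gmt"], pairs_path=paths["pairs"],
            labels_path=paths["labels"], step=10, k_folds=5,
        )
        defaults.update(kw)
        return PipelineConfig(**defaults)

    def test_all_artifacts_written(self, fixture_dir, tmp_path):
        manifest = run_pipeline(self._config(fixture_dir), tmp_path / "run")
        out = tmp_path / "run"
        for name in (
            "ranked_features.tsv", "ifs_curve.tsv", "ifs_curve.png",
            "optimum_metrics.json", "final_tree.json", "rules.json",
            "rules.txt", "manifest.json",
        ):
            assert (out / name).exists(), name
        assert manifest["n_rules"] == (
            manifest["n_identifying_rules"] + manifest["n_excluding_rules"]
        )

    def test_rerun_byte_identical(self, fixture_dir, tmp_path):
        run_pipeline(self._config(fixture_dir), tmp_path / "a")
        run_pipeline(self._config(fixture_dir), tmp_path / "b")
        for name in ("ranked_features.tsv", "ifs_curve.tsv", "rules.json",
                     "final_tree.json", "manifest.json", "rules.txt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_stage_failure_reports_stage(self, fixture_dir, tmp_path):
        cfg = self._config(fixture_dir, labels_path=fixture_dir["gmt"])
        with pytest.raises(RuntimeError, match="load inputs"):
            run_pipeline(cfg, tmp_path / "bad")

    def test_invalid_config_rejected(self, fixture_dir):
        with pytest.raises(ValueError):
            self._config(fixture_dir, step=0).validate()
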