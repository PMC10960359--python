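"""Random-forest training, cross-validation, and genome-wide scoring."""

import numpy as np
import pytest

from netprop import (
    FeatureMatrix,
    ForestConfig,
    GeneSet,
    LabelSpec,
    TrainedModel,
    cross_validate,
    generate_benchmark,
    predict_scores,
    sample_negatives,
    train_full,
)
from netprop.synthetic_data import BenchmarkConfig


def _toy_features(n_pos=15, n_neg=15, n_bg=30, noise_seed=0):
    """Perfectly separable toy: positives' features 1, everyone else's 0."""
    rng = np.random.default_rng(noise_seed)
    genes = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)] + [
        f"b{i}" for i in range(n_bg)
    ]
    values = np.zeros((len(genes), 3))
    values[:n_pos] = 1.0
    values += rng.normal(0, 1e-6, values.shape)  # break exact ties
    return (
        FeatureMatrix(tuple(genes), ("f1", "f2", "f3"), values, {}),
        GeneSet("positives", tuple(genes[:n_pos])),
        GeneSet("negatives", tuple(genes[n_pos : n_pos + n_neg])),
    )


class TestSampleNegatives:
    def test_counts_and_pool(self, default_benchmark):
        spec = LabelSpec(
            positives=default_benchmark.positives,
            exclusion=default_benchmark.exclusion,
            rng_seed=0,
        )
        neg = sample_negatives(default_benchmark.network, spec)
        assert len(neg) == len(default_benchmark.positives)
        assert not set(neg.genes) & set(default_benchmark.exclusion.genes)

    def test_deterministic_under_seed(self, default_benchmark):
        spec = LabelSpec(
            positives=default_benchmark.positives,
            exclusion=default_benchmark.exclusion,
            rng_seed=5,
        )
        a = sample_negatives(default_benchmark.network, spec)
        b = sample_negatives(default_benchmark.network, spec)
        assert a.genes == b.genes

    def test_ratio_scales_sample(self, default_benchmark):
        spec = LabelSpec(
            positives=default_benchmark.positives,
            exclusion=default_benchmark.exclusion,
            negative_ratio=2.0,
            rng_seed=0,
        )
        neg = sample_negatives(default_benchmark.network, spec)
        assert len(neg) == 2 * len(default_benchmark.positives)

    def test_pool_too_small_reports_counts(self):
        fm, pos, _ = _toy_features(n_pos=15, n_neg=15, n_bg=5)
        exclusion = GeneSet("excl", fm.genes[:40])
        spec = LabelSpec(positives=pos, exclusion=exclusion, rng_seed=0)

        class _Net:
            nodes = fm.genes
            n_nodes = len(fm.genes)

            def __contains__(self, g):
                return g in set(fm.genes)

        with pytest.raises(ValueError, match="pool too small"):
            sample_negatives(_Net(), spec)

    def test_positives_must_be_excluded(self):
        with pytest.raises(ValueError, match="not covered"):
            LabelSpec(
                positives=GeneSet("p", ("a", "b")),
                exclusion=GeneSet("e", ("a",)),
            )


class TestCrossValidate:
    def test_separable_toy_is_perfect(self):
        fm, pos, neg = _toy_features()
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        cv = cross_validate(fm, spec, ForestConfig(rng_seed=0), negatives=neg)
        assert cv.mean_auroc == pytest.approx(1.0)
        assert cv.mean_auprc == pytest.approx(1.0)

    def test_means_are_arithmetic_means_of_folds(self, default_cv):
        assert default_cv.mean_auroc == pytest.approx(
            np.mean([f.auroc for f in default_cv.per_fold]), abs=0
        )
        assert default_cv.mean_auprc == pytest.approx(
            np.mean([f.auprc for f in default_cv.per_fold]), abs=0
        )
        assert len(default_cv.per_fold) == 5
        assert all(0 <= f.auroc <= 1 and 0 <= f.auprc <= 1
                   for f in default_cv.per_fold)

    def test_folds_partition_labeled_genes(self, default_cv, default_benchmark):
        oof = set(default_cv.oof_scores)
        assert len(default_cv.oof_scores) == len(default_cv.oof_labels) == 100
        assert set(default_benchmark.positives.genes) <= oof

    def test_deterministic_across_runs(self, default_benchmark, default_features):
        spec = LabelSpec(
            positives=default_benchmark.positives,
            exclusion=default_benchmark.exclusion,
            rng_seed=7,
        )
        a = cross_validate(default_features, spec, ForestConfig(rng_seed=7))
        b = cross_validate(default_features, spec, ForestConfig(rng_seed=7))
        assert a.mean_auroc == b.mean_auroc
        assert a.oof_scores == b.oof_scores

    def test_absent_positive_dropped_with_warning(self, caplog):
        import logging

        fm, pos, neg = _toy_features()
        ghost = GeneSet("positives", pos.genes + ("ghost1",))
        spec = LabelSpec(positives=ghost, exclusion=ghost, rng_seed=0)
        with caplog.at_level(logging.WARNING):
            cv = cross_validate(fm, spec, ForestConfig(rng_seed=0), negatives=neg)
        assert "ghost1" not in cv.oof_scores
        assert any("absent" in r.message for r in caplog.records)

    def test_missing_explicit_negative_listed(self):
        fm, pos, _ = _toy_features()
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        bad_neg = GeneSet("negatives", ("n0", "n1", "ghost2"))
        with pytest.raises(KeyError, match="ghost2"):
            cross_validate(fm, spec, ForestConfig(rng_seed=0), negatives=bad_neg)

    def test_too_few_per_class_rejected(self):
        fm, pos, neg = _toy_features(n_pos=3, n_neg=3)
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        with pytest.raises(ValueError, match="per class"):
            cross_validate(fm, spec, ForestConfig(rng_seed=0), negatives=neg)

    def test_permuted_labels_sit_at_chance(self, small_benchmark):
        """Mean permuted-label AUROC over 20 permutations is ~0.5."""
        bench = generate_benchmark(small_benchmark)
        from netprop import build_feature_matrix

        fm = build_feature_matrix(bench.network, bench.seed_sets)
        spec = LabelSpec(
            positives=bench.positives, exclusion=bench.exclusion, rng_seed=0
        )
        neg = sample_negatives(bench.network, spec)
        labeled = list(bench.positives.genes) + list(neg.genes)
        n_pos = len(bench.positives)
        aurocs = []
        for ps in range(20):
            rng = np.random.default_rng(ps)
            perm = list(rng.permutation(labeled))
            ppos = GeneSet("positives", tuple(perm[:n_pos]))
            pneg = GeneSet("negatives", tuple(perm[n_pos:]))
            pspec = LabelSpec(positives=ppos, exclusion=ppos, rng_seed=ps)
            cv = cross_validate(fm, pspec, ForestConfig(rng_seed=ps),
                                negatives=pneg)
            aurocs.append(cv.mean_auroc)
        # 20 x 40 labeled genes: ~3 sigma band around chance
        assert abs(np.mean(aurocs) - 0.5) < 0.08


class TestTrainPredict:
    def test_scores_in_unit_interval(self, default_benchmark, default_features):
        spec = LabelSpec(
            positives=default_benchmark.positives,
            exclusion=default_benchmark.exclusion,
            rng_seed=7,
        )
        model = train_full(default_features, spec, ForestConfig(rng_seed=7))
        scores = predict_scores(model, default_features)
        assert scores.kind == "classifier"
        assert ((scores.values >= 0) & (scores.values <= 1)).all()

    def test_persistence_round_trip(self, tmp_path):
        fm, pos, neg = _toy_features()
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        model = train_full(fm, spec, ForestConfig(rng_seed=0), negatives=neg)
        before = predict_scores(model, fm).values
        model.save(tmp_path / "model.joblib")
        reloaded = TrainedModel.load(tmp_path / "model.joblib")
        assert np.array_equal(predict_scores(reloaded, fm).values, before)

    def test_separable_toy_orders_all_positives_first(self):
        fm, pos, neg = _toy_features()
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        model = train_full(fm, spec, ForestConfig(rng_seed=0), negatives=neg)
        scores = predict_scores(model, fm).to_dict()
        assert min(scores[g] for g in pos.genes) > max(
            scores[g] for g in neg.genes
        )

    def test_mismatched_columns_rejected(self):
        fm, pos, neg = _toy_features()
        spec = LabelSpec(positives=pos, exclusion=pos, rng_seed=0)
        model = train_full(fm, spec, ForestConfig(rng_seed=0), negatives=neg)
        renamed = FeatureMatrix(fm.genes, ("x1", "x2", "x3"), fm.values, {})
        with pytest.raises(ValueError, match="columns"):
            predict_scores(model, renamed)

    def test_forest_config_validated(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=0)
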