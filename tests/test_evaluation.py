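import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom
from sklearn.metrics import average_precision_score, roc_auc_score

from _oracles import pairwise_concordance_auc, threshold_enumeration_aupr
from lncdbn.evaluation import (
    CVSpec,
    MetricError,
    PipelineConfig,
    SamplingError,
    SplitError,
    cross_validate_cancer,
    evaluate_all,
    kfold_split,
    pr_auc,
    rank_candidates,
    roc_auc,
    sample_negatives,
)


class TestROCAUC:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            ours = roc_auc(scores, labels)
            assert abs(ours - pairwise_concordance_auc(scores, labels)) < 1e-12
            assert abs(ours - roc_auc_score(labels, scores)) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.random(20)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores) + 1, labels) == pytest.approx(base)


class TestPRAUC:
    def test_perfect_ranking(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.1, 0.05]
        labels = [1] * 5 + [0] * 5
        assert pr_auc(scores, labels) == 1.0

    def test_matches_enumeration_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            ours = pr_auc(scores, labels)
            assert abs(ours - threshold_enumeration_aupr(scores, labels)) < 1e-12
            assert abs(ours - average_precision_score(labels, scores)) < 1e-10

    def test_random_scores_near_prevalence(self, rng):
        """Monte-Carlo: random-score AUPR sits at the prevalence baseline
        (upward-biased at finite n) and matches the enumeration oracle rep
        by rep."""
        labels = np.r_[np.ones(10), np.zeros(40)].astype(int)
        draws = [rng.random(50) for _ in range(300)]
        vals = np.array([pr_auc(s, labels) for s in draws])
        oracle = np.array([threshold_enumeration_aupr(s, labels) for s in draws[:50]])
        assert np.allclose(vals[:50], oracle, atol=1e-12)
        assert 0.2 <= vals.mean() <= 0.32

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            pr_auc([0.5, 0.4], [0, 0])

    def test_bounded(self, rng):
        for _ in range(10):
            scores = rng.random(30)
            labels = np.r_[np.ones(3), np.zeros(27)].astype(int)
            assert 0.0 <= pr_auc(scores, labels) <= 1.0


class TestNegativeSampling:
    def test_size_and_disjointness(self, tiny_dataset):
        cancer = next(iter(tiny_dataset.associations))
        negs = sample_negatives(tiny_dataset, cancer, 1.0, seed=0)
        positives = tiny_dataset.associations[cancer]
        assert len(negs) == len(positives)
        assert not set(negs) & positives

    def test_deterministic(self, tiny_dataset):
        cancer = next(iter(tiny_dataset.associations))
        assert sample_negatives(tiny_dataset, cancer, 1.0, 7) == sample_negatives(
            tiny_dataset, cancer, 1.0, 7
        )

    def test_insufficient_candidates(self, tiny_dataset):
        cancer = next(iter(tiny_dataset.associations))
        with pytest.raises(SamplingError):
            sample_negatives(tiny_dataset, cancer, 100.0, 0)

    def test_inclusion_uniform_across_seeds(self, tiny_dataset):
        """Each candidate's inclusion frequency stays inside binomial 99%
        bounds over 200 seeds."""
        cancer = next(iter(tiny_dataset.associations))
        positives = tiny_dataset.associations[cancer]
        candidates = sorted(set(tiny_dataset.lncrna_ids) - positives)
        n_draw = len(positives)
        p = n_draw / len(candidates)
        counts = {c: 0 for c in candidates}
        n_rep = 200
        for seed in range(n_rep):
            for lnc in sample_negatives(tiny_dataset, cancer, 1.0, seed):
                counts[lnc] += 1
        # ~50 candidates are tested at once: use 0.1% tails with slack so the
        # family-wise false-alarm rate stays negligible
        lo = binom.ppf(0.0005, n_rep, p) - 2
        hi = binom.isf(0.0005, n_rep, p) + 2
        assert all(lo <= c <= hi for c in counts.values())


class TestKFold:
    def test_even_partition(self):
        ids = [f"L{i}" for i in range(20)]
        labels = [1] * 10 + [0] * 10
        assignment = kfold_split(ids, labels, CVSpec(k=10, experiment_seed=1))
        sizes = np.bincount(assignment, minlength=10)
        assert np.all(sizes == 2)

    def test_stratified_class_balance(self):
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assignment = kfold_split(
            [str(i) for i in range(20)], labels, CVSpec(k=10, experiment_seed=0)
        )
        for fold in range(10):
            fold_labels = labels[assignment == fold]
            assert sorted(fold_labels) == [0, 1]

    def test_every_sample_in_one_test_fold(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:10] = 1
        labels[10:20] = 0
        assignment = kfold_split(
            [str(i) for i in range(40)], labels, CVSpec(k=5, experiment_seed=2)
        )
        assert assignment.shape == (40,)
        assert set(assignment) == set(range(5))

    def test_too_few_positives_rejected(self):
        labels = [1] * 3 + [0] * 17
        with pytest.raises(SplitError):
            kfold_split([str(i) for i in range(20)], labels, CVSpec(k=10))


@pytest.fixture(scope="module")
def cv_result(tiny_dataset, fast_cv, fast_config):
    cancer = next(iter(tiny_dataset.associations))
    return cross_validate_cancer(tiny_dataset, cancer, "dbn-cnn", fast_cv, fast_config)


@pytest.fixture(scope="module")
def eval_result(tiny_dataset, fast_cv, fast_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    res = evaluate_all(
        tiny_dataset, ["dbn-cnn", "dbn-dnn"], fast_cv, fast_config, outdir=out
    )
    return res, out


class TestCrossValidation:
    def test_per_fold_metric_count(self, cv_result, fast_cv):
        assert len(cv_result.fold_auc) == fast_cv.k
        assert len(cv_result.fold_aupr) == fast_cv.k
        assert all(0 <= a <= 1 for a in cv_result.fold_auc)

    def test_held_out_scores_cover_each_sample_once(self, cv_result):
        assert len(cv_result.held_out_scores) == len(cv_result.sample_ids)
        assert np.all(np.isfinite(cv_result.held_out_scores))
        assert len(set(cv_result.sample_ids)) == len(cv_result.sample_ids)

    def test_fold_parity_across_methods(self, tiny_dataset, fast_cv, fast_config):
        cancer = next(iter(tiny_dataset.associations))
        results = [
            cross_validate_cancer(tiny_dataset, cancer, m, fast_cv, fast_config)
            for m in ("dbn-cnn", "pca-cnn", "dbn-dnn")
        ]
        for r in results[1:]:
            assert r.sample_ids == results[0].sample_ids
            assert np.array_equal(r.fold_assignment, results[0].fold_assignment)

    def test_unknown_cancer_rejected(self, tiny_dataset, fast_cv):
        with pytest.raises(KeyError):
            cross_validate_cancer(tiny_dataset, "nope", "dbn-cnn", fast_cv)


class TestEvaluateAll:
    def test_macro_equals_mean_of_per_cancer_column(self, eval_result):
        result, _ = eval_result
        table = result.per_cancer_table()
        sub = table[table.method == "dbn-cnn"]
        assert result.macro_auc("dbn-cnn") == pytest.approx(sub.auc.mean())
        assert result.macro_aupr("dbn-cnn") == pytest.approx(sub.aupr.mean())

    def test_pooled_equals_metric_on_concatenation(self, eval_result):
        result, _ = eval_result
        scores, labels = result.pooled_scores("dbn-cnn")
        assert result.pooled_auc("dbn-cnn") == pytest.approx(roc_auc(scores, labels))

    def test_single_cancer_pooled_matches_cancer_pooled(self, eval_result):
        result, _ = eval_result
        only = result.for_method("dbn-cnn")[0]
        assert result.pooled_auc("dbn-cnn") == pytest.approx(only.pooled_auc)

    def test_report_files_and_schema(self, eval_result):
        import pandas as pd
        import yaml

        _, out = eval_result
        table = pd.read_csv(out / "per_cancer_metrics.tsv", sep="\t")
        assert {"cancer", "method", "auc", "aupr", "summary_type"} <= set(table.columns)
        roc = pd.read_csv(out / "pooled_roc.tsv", sep="\t")
        assert {"method", "threshold", "fpr", "tpr"} <= set(roc.columns)
        # ROC sweep is monotone non-decreasing in both coordinates
        for _, grp in roc.groupby("method"):
            assert np.all(np.diff(grp.fpr) >= 0)
            assert np.all(np.diff(grp.tpr) >= 0)
        with open(out / "summary.yaml") as fh:
            summary = yaml.safe_load(fh)
        for m in ("dbn-cnn", "dbn-dnn"):
            assert summary["methods"][m]["pooled"]["summary_type"] == "pooled"
            assert summary["methods"][m]["macro"]["summary_type"] == "macro"


class TestRankCandidates:
    def test_positives_excluded_and_length(self, tiny_dataset, fast_cv, fast_config):
        cancer = next(iter(tiny_dataset.associations))
        ranking = rank_candidates(
            tiny_dataset, cancer, "dbn-dnn", fast_cv, fast_config
        )
        positives = tiny_dataset.associations[cancer]
        ranked_ids = {r[1] for r in ranking}
        assert not ranked_ids & positives
        assert len(ranking) == len(tiny_dataset.lncrna_ids) - len(positives)
        scores = [r[2] for r in ranking]
        assert scores == sorted(scores, reverse=True)
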