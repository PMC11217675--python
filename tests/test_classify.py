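"""Classification protocol: scaling, models, evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracle
from ucnescan import classify, features
from ucnescan.classify import (EvalReport, ModelConfig, roc_auc, train_eval,
                               zscore_apply, zscore_fit)
from ucnescan.features import FEATURE_NAMES, FeatureTable


def _table_from_arrays(X, y):
    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    frame.insert(0, "ID", [f"s{i}" for i in range(len(y))])
    frame["Class"] = y
    return FeatureTable(frame)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs in feature space (n=200)."""
    rng = np.random.default_rng(99)
    X0 = rng.normal(0.0, 1.0, size=(100, 9))
    X1 = rng.normal(8.0, 1.0, size=(100, 9))
    X = np.vstack([X0, X1])
    y = np.array([0] * 100 + [1] * 100)
    return _table_from_arrays(X, y)


class TestZscore:
    def test_three_point_hand_case(self):
        scaler = zscore_fit(np.array([[1.0], [2.0], [3.0]]), columns=["F1"])
        z = zscore_apply(scaler, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_train_statistics_applied_to_test(self):
        train = np.array([[0.0], [10.0]])
        scaler = zscore_fit(train, columns=["F1"])
        z = zscore_apply(scaler, np.array([[20.0]]))
        assert z[0, 0] == pytest.approx((20 - 5) / np.std([0, 10], ddof=1))

    def test_not_idempotent(self):
        X = np.array([[1.0], [2.0], [4.0]])
        scaler = zscore_fit(X, columns=["F1"])
        once = zscore_apply(scaler, X)
        twice = zscore_apply(scaler, once)
        assert not np.allclose(once, twice)

    def test_constant_column_named_in_error(self):
        X = np.ones((5, 9))
        X[:, :8] = np.random.default_rng(0).normal(size=(5, 8))
        with pytest.raises(ValueError, match="F9"):
            zscore_fit(X)

    def test_column_rescaling_cancels(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 9))
        Xs = X * 7.3
        z1 = zscore_apply(zscore_fit(X), X)
        z2 = zscore_apply(zscore_fit(Xs), Xs)
        np.testing.assert_allclose(z1, z2, rtol=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_all_ties_half_credit(self):
        auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_mann_whitney_identity(self, rng):
        """Trapezoidal AUC equals the normalized Mann-Whitney U statistic."""
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n).round(1)  # ties included
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            n1, n0 = labels.sum(), (1 - labels).sum()
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-9)

    def test_equals_pair_counting_oracle(self, rng):
        scores = rng.normal(size=60).round(1)
        labels = np.array([0, 1] * 30)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle.pair_auc(scores, labels), abs=1e-12)

    def test_random_scores_give_half(self, rng):
        scores = rng.normal(size=1000)
        labels = np.array([0, 1] * 500)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)


class TestTrainEval:
    @pytest.mark.parametrize("model", classify.MODEL_NAMES)
    def test_separable_blobs_are_perfect(self, blobs, model):
        report = train_eval(blobs, ModelConfig(model=model, seed=5))
        assert report.accuracy == 1.0
        assert report.auc == 1.0

    def test_shuffled_labels_are_chance(self, small_table):
        rng = np.random.default_rng(17)
        frame = small_table.frame.copy()
        frame["Class"] = rng.permutation(frame["Class"].to_numpy())
        report = train_eval(FeatureTable(frame), ModelConfig(seed=17))
        n = report.n_test
        # binomial 3-sigma band around 0.5
        assert abs(report.accuracy - 0.5) < 3 * np.sqrt(0.25 / n) + 1e-9
        assert abs(report.auc - 0.5) < 0.2

    def test_svm_deterministic(self, small_table):
        r1 = train_eval(small_table, ModelConfig(model="svm_rbf", seed=3))
        r2 = train_eval(small_table, ModelConfig(model="svm_rbf", seed=3))
        assert r1.to_dict() == r2.to_dict()

    def test_metrics_recompute_from_confusion(self, small_table):
        r = train_eval(small_table, ModelConfig(model="svm_rbf", seed=8))
        assert r.tp + r.fp + r.tn + r.fn == r.n_test
        assert r.sensitivity == r.tp / (r.tp + r.fn)
        assert r.specificity == r.tn / (r.tn + r.fp)
        assert r.accuracy == (r.tp + r.tn) / r.n_test
        lo, hi = r.accuracy_ci95
        assert 0 <= lo <= r.accuracy <= hi <= 1

    def test_clopper_pearson_against_scipy(self):
        report = EvalReport(tp=40, fp=5, tn=45, fn=10, auc=0.9,
                            roc_points=[], config=ModelConfig())
        lo, hi = report.accuracy_ci95
        ref = stats.binomtest(85, 100).proportion_ci(0.95, method="exact")
        assert lo == pytest.approx(ref.low)
        assert hi == pytest.approx(ref.high)

    def test_single_class_table_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 9))
        with pytest.raises(ValueError):
            train_eval(_table_from_arrays(X, np.ones(20, dtype=int)),
                       ModelConfig())

    def test_ann_weight_cap_enforced(self, blobs):
        with pytest.raises(ValueError, match="cap"):
            train_eval(blobs, ModelConfig(model="ann", ann_hidden_units=200,
                                          ann_max_weights=1000))

    @pytest.mark.parametrize("model", classify.MODEL_NAMES)
    def test_feature_rescaling_leaves_predictions_unchanged(
            self, small_table, model):
        """Any positive per-column rescaling cancels in z-normalization, so
        the ambiguity in the feature units cannot affect the classifiers."""
        frame = small_table.frame.copy()
        frame["F5"] = frame["F5"] * 7.3
        r1 = train_eval(small_table, ModelConfig(model=model, seed=2))
        r2 = train_eval(FeatureTable(frame), ModelConfig(model=model, seed=2))
        assert (r1.tp, r1.fp, r1.tn, r1.fn) == (r2.tp, r2.fp, r2.tn, r2.fn)


class TestRepeatedEval:
    def test_outputs_one_accuracy_per_subset(self, small_benchmark):
        from ucnescan.synthetic import default_negative_spec, markov_generate
        neg_spec = default_negative_spec()

        def sampler(seed):
            return markov_generate(neg_spec, 150, seed, prefix=f"c{seed}")

        result = classify.repeated_eval(
            small_benchmark.positives, sampler,
            ModelConfig(model="svm_rbf", seed=1), n_subsets=3, seed=5)
        assert len(result.accuracies) == 3
        assert 0 < result.mean <= 1
        assert result.sd >= 0

    def test_requires_two_subsets(self, small_benchmark):
        with pytest.raises(ValueError):
            classify.repeated_eval(small_benchmark.positives, lambda s: [],
                                   ModelConfig(), n_subsets=1)
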