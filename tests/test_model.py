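import numpy as np
import pytest

from redpep.encoding import ProteinRecord, encode_dataset
from redpep.errors import (
    ConfigurationError,
    EncodingMismatchError,
    StratificationError,
    UndefinedMetricError,
)
from redpep.model import (
    ConfusionCounts,
    SVMConfig,
    compute_metrics,
    cross_validate,
    cv_accuracy,
    default_grid,
    grid_search,
    predict,
    roc_auc,
    train_final,
    FittedModel,
)

from .conftest import make_matrix


def pair_count_auc(scores, labels):
    """Oracle: P(score+ > score-) + 1/2 P(tie) over all pos-neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_worked_example(self):
        sn, sp, acc = compute_metrics(ConfusionCounts(TP=3, TN=4, FP=2, FN=1))
        assert sn == pytest.approx(0.75)
        assert sp == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.70)

    def test_all_correct(self):
        sn, sp, acc = compute_metrics(ConfusionCounts(TP=5, TN=7, FP=0, FN=0))
        assert (sn, sp, acc) == (1.0, 1.0, 1.0)

    def test_no_positives_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(TP=0, TN=4, FP=2, FN=0))

    def test_no_negatives_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(TP=3, TN=0, FP=0, FN=1))

    @pytest.mark.parametrize("tp,tn,fp,fn", [
        (1, 1, 0, 0), (2, 3, 1, 1), (0, 5, 0, 3), (4, 0, 6, 1),
    ])
    def test_enumerated_small_confusions(self, tp, tn, fp, fn):
        sn, sp, acc = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert sn == pytest.approx(tp / (tp + fn))
        assert sp == pytest.approx(tn / (tn + fp))
        assert acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc(np.array([1.0, 1.0, 0.0]), np.array([1, 1, 0]))
        assert auc == pytest.approx(1.0)
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)

    def test_all_scores_identical_is_half(self):
        _, auc = roc_auc(np.zeros(6), np.array([1, 0, 1, 0, 1, 0]))
        assert auc == pytest.approx(0.5)

    def test_worked_example_075(self):
        _, auc = roc_auc(
            np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 0, 1, 0])
        )
        assert auc == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_points_monotone_and_anchored(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        points, _ = roc_auc(scores, labels)
        fprs = [p[0] for p in points]
        tprs = [p[1] for p in points]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(30):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            # discretized scores force ties to be exercised
            scores = np.round(rng.normal(size=n), 1)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-9
            )


class TestGridSearch:
    def test_default_grid_has_90_candidates(self):
        grid = default_grid()
        assert len(grid) == 90
        assert len({g.C for g in grid}) == 10
        assert len({g.gamma for g in grid}) == 9
        for g in grid:
            assert 2.0**-5 < g.C < 2.0**15
            assert 2.0**-15 < g.gamma < 2.0**3

    def test_single_config_returned(self, separable_matrix):
        only = SVMConfig(4.0, 1.0)
        best, _ = grid_search(separable_matrix, [only], seed=1)
        assert best == only

    def test_empty_grid(self, separable_matrix):
        with pytest.raises(ConfigurationError):
            grid_search(separable_matrix, [], seed=1)

    def test_tie_prefers_smaller_c_then_gamma(self, separable_matrix):
        # fully separable: many configs reach accuracy 1.0
        grid = [SVMConfig(c, g) for c in (1.0, 8.0) for g in (0.5, 2.0)]
        best, acc = grid_search(separable_matrix, grid, seed=1)
        assert acc == 1.0
        assert best == SVMConfig(1.0, 0.5)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            SVMConfig(-1.0, 1.0)


class TestCrossValidate:
    def test_separable_reaches_perfect_scores(self, separable_matrix):
        report = cross_validate(separable_matrix, SVMConfig(8, 2), seed=1)
        assert report.acc == 1.0
        assert report.auc == pytest.approx(1.0)
        assert report.sn == 1.0 and report.sp == 1.0

    def test_null_band_on_permuted_labels(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(200, 10))
        y = np.array([1, 0] * 100)
        report = cross_validate(make_matrix(X, y), SVMConfig(8, 2), seed=1)
        assert 0.35 <= report.acc <= 0.65

    def test_same_seed_identical_reports(self, separable_matrix):
        r1 = cross_validate(separable_matrix, SVMConfig(8, 2), seed=3)
        r2 = cross_validate(separable_matrix, SVMConfig(8, 2), seed=3)
        assert r1.to_text() == r2.to_text()

    def test_confusion_partitions_classes(self, separable_matrix):
        report = cross_validate(separable_matrix, SVMConfig(8, 2), seed=1)
        c = report.confusion
        y = separable_matrix.labels
        assert c.TP + c.FN == int(np.sum(y == 1))
        assert c.TN + c.FP == int(np.sum(y == 0))
        assert report.acc == (c.TP + c.TN) / c.n

    def test_stratification_error(self):
        m = make_matrix(np.zeros((8, 2)), [1, 1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(StratificationError):
            cross_validate(m, SVMConfig(1, 1), folds=5, seed=1)

    def test_stratified_fold_proportions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 20 + [0] * 40)
        from redpep.model import _stratified_folds

        for _, test in _stratified_folds(y, 5, seed=1):
            n_pos = int(np.sum(y[test] == 1))
            assert abs(n_pos - 4) <= 1

    def test_cv_accuracy_mean_of_folds(self, separable_matrix):
        acc = cv_accuracy(separable_matrix, SVMConfig(8, 2), seed=1)
        assert acc == 1.0


class TestTrainPredict:
    def records(self):
        rng = np.random.default_rng(17)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        return [
            ProteinRecord(
                f"r{i}", "".join(rng.choice(letters, 60)), i % 2
            )
            for i in range(20)
        ]

    def test_training_accuracy_on_separable(self, separable_matrix):
        model = train_final(separable_matrix, SVMConfig(8, 2))
        pred, _ = predict(model, separable_matrix)
        assert np.mean(pred == separable_matrix.labels) == 1.0

    def test_scheme_mismatch_rejected(self, size2, size10):
        recs = self.records()
        m2 = encode_dataset(recs, size2, 2)
        m10 = encode_dataset(recs, size10, 2)
        model = train_final(m2, SVMConfig(8, 2))
        with pytest.raises(EncodingMismatchError):
            predict(model, m10)

    def test_n_mismatch_rejected(self, size2):
        recs = self.records()
        model = train_final(encode_dataset(recs, size2, 2), SVMConfig(8, 2))
        with pytest.raises(EncodingMismatchError):
            predict(model, encode_dataset(recs, size2, 1))

    def test_save_load_roundtrip(self, tmp_path, size2):
        recs = self.records()
        m = encode_dataset(recs, size2, 2)
        model = train_final(m, SVMConfig(8, 2))
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = FittedModel.load(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.config == model.config
        p1, s1 = predict(model, m)
        p2, s2 = predict(loaded, m)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(s1, s2)

    def test_predict_selects_model_features(self, size2):
        recs = self.records()
        m = encode_dataset(recs, size2, 2)
        sub = m.select_columns(m.feature_names[:2])
        model = train_final(sub, SVMConfig(8, 2))
        pred_full, _ = predict(model, m)  # model restricts to its columns
        pred_sub, _ = predict(model, sub)
        np.testing.assert_array_equal(pred_full, pred_sub)
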