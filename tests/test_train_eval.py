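"""Splits, training protocol, metric oracles and attribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaussflex import (
    ModelSpec,
    TrainConfig,
    bootstrap_ci,
    build_model,
    confusion_and_calibration,
    cross_validate_then_retrain,
    holdout_split,
    integrated_gradients,
    make_labeled_set,
    pr_metrics,
    regression_metrics,
    roc_auc,
    stratified_kfold,
    train,
    youden,
)
from gaussflex.autodiff import Tensor
from gaussflex.errors import (
    CapabilityError,
    MetricError,
    ParameterError,
    StratificationError,
)
from gaussflex.train_eval import per_cluster_auc


class TestHoldoutSplit:
    def test_study_sizes(self):
        """1,374 chains split into a 275 test set and 1,099 training pool."""
        train_idx, test_idx = holdout_split(1374, 0.2, seed=0)
        assert len(test_idx) == 275
        assert len(train_idx) == 1099

    def test_even_split(self):
        tr, te = holdout_split(10, 0.5, seed=1)
        assert len(tr) == len(te) == 5
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 10

    def test_seed_determinism(self):
        assert np.array_equal(holdout_split(100, 0.2, seed=7)[1],
                              holdout_split(100, 0.2, seed=7)[1])

    def test_stratified_per_class_rounding(self):
        labels = np.array([0] * 70 + [1] * 30)
        tr, te = holdout_split(100, 0.2, seed=2, stratify_labels=labels)
        assert len(te) == 20
        assert np.sum(labels[te] == 0) == 14
        assert np.sum(labels[te] == 1) == 6

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ParameterError):
            holdout_split(5, 0.01, seed=0)


class TestStratifiedKFold:
    def test_balanced_hundred(self):
        labels = np.array([0, 1] * 50)
        folds = stratified_kfold(labels, k=5, seed=0)
        for fold in folds:
            assert len(fold) == 20
            assert np.sum(labels[fold] == 0) == 10

    def test_folds_partition_indices(self):
        labels = np.array([0] * 33 + [1] * 44)
        folds = stratified_kfold(labels, k=5, seed=1)
        allidx = np.concatenate(folds)
        assert len(allidx) == 77
        assert len(np.unique(allidx)) == 77

    def test_seed_determinism(self):
        labels = np.array([0, 1] * 20)
        f1 = stratified_kfold(labels, k=4, seed=3)
        f2 = stratified_kfold(labels, k=4, seed=3)
        for a, b in zip(f1, f2):
            assert np.array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_kfold(np.array([0] * 20 + [1] * 3), k=5, seed=0)


class TestTrainingLoop:
    def test_learnable_data_reduces_validation_loss(self):
        ds = make_labeled_set(400, (1, 2), 2.0, 0.2, seed=0)
        model = build_model(ModelSpec(architecture="cnn", seed=0))
        _, hist = train(model, (ds.X[:300], ds.y[:300], ds.X[300:], ds.y[300:]),
                        TrainConfig(seed=0, max_epochs=25))
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert min(hist["val_loss"]) < 0.5

    def test_patience_bounds_overrun(self):
        ds = make_labeled_set(120, (), 0.0, 1.0, seed=1)  # pure noise
        model = build_model(ModelSpec(architecture="cnn", seed=1))
        cfg = TrainConfig(seed=1, patience=4, max_epochs=50)
        _, hist = train(model, (ds.X[:90], ds.y[:90], ds.X[90:], ds.y[90:]), cfg)
        epochs = len(hist["val_loss"])
        assert epochs <= hist["best_epoch"] + cfg.patience + 1
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"]))

    def test_same_seed_identical_history(self):
        ds = make_labeled_set(200, (1,), 1.5, 0.5, seed=2)
        runs = []
        for _ in range(2):
            model = build_model(ModelSpec(architecture="cnn", seed=2))
            _, hist = train(
                model, (ds.X[:150], ds.y[:150], ds.X[150:], ds.y[150:]),
                TrainConfig(seed=2, max_epochs=6),
            )
            runs.append(hist)
        assert runs[0]["train_loss"] == runs[1]["train_loss"]
        assert runs[0]["val_loss"] == runs[1]["val_loss"]


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def cv_run(self):
        ds = make_labeled_set(250, (1, 2), 2.0, 0.3, seed=3)
        spec = ModelSpec(architecture="cnn", seed=3)
        cfg = TrainConfig(seed=3, max_epochs=8)
        model, report = cross_validate_then_retrain(ds.X, ds.y, spec, cfg)
        return ds, model, report

    def test_report_structure(self, cv_run):
        _, _, report = cv_run
        assert len(report.fold_metrics) == 5
        assert 0 <= report.selected_fold < 5

    def test_selected_fold_is_argmax(self, cv_run):
        _, _, report = cv_run
        best = report.fold_metrics[report.selected_fold]["val_metric"]
        assert all(best >= m["val_metric"] for m in report.fold_metrics)

    def test_holdout_untouched(self, cv_run):
        ds, _, report = cv_run
        assert len(report.holdout_indices) == round(0.2 * 250)
        assert len(np.unique(report.holdout_indices)) == len(report.holdout_indices)

    def test_svm_path(self):
        ds = make_labeled_set(200, (1, 2), 2.0, 0.3, seed=4)
        spec = ModelSpec(architecture="svm_rbf", seed=4)
        model, report = cross_validate_then_retrain(
            ds.X, ds.y, spec, TrainConfig(seed=4)
        )
        assert roc_auc(report.holdout_labels, report.holdout_scores) > 0.8


class TestAUC:
    def test_worked_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_pair_counting_oracle(self):
        """AUC equals concordant-pair counting with half credit for ties."""
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=30), 1)  # induce ties
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(labels, scores) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        scores = rng.normal(size=20)
        a1 = roc_auc(labels, scores)
        a2 = roc_auc(labels, np.exp(2.0 * scores) + 3.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_bootstrap_ci_covers_point_estimate(self):
        hits = 0
        for seed in range(20):
            ds = make_labeled_set(100, (1,), 1.2, 0.8, seed=seed)
            scores = ds.X[:, 0] + np.random.default_rng(seed).normal(scale=1.0, size=100)
            auc = roc_auc(ds.y, scores)
            lo, hi = bootstrap_ci(ds.y, scores, n_boot=300, seed=seed)
            hits += lo <= auc <= hi
        assert hits >= 19


class TestPRAndYouden:
    def test_perfect_ranking(self):
        res = pr_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert res["average_precision"] == 1.0
        assert res["max_f1"] == 1.0

    def test_youden_two_point_example(self):
        thr = youden([1, 0], [0.9, 0.1])
        assert 0.1 < thr <= 0.9
        # J at that threshold is 1 (TPR 1, FPR 0) under the >= rule
        assert 0.9 >= thr and not (0.1 >= thr)

    def test_ap_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(6)
        labels = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 0])
        scores = np.round(rng.uniform(size=10), 2)
        # step-wise area: sum over descending thresholds of dRecall * precision
        order = np.argsort(-scores, kind="stable")
        ap = 0.0
        tp = fp = 0
        n_pos = labels.sum()
        last_recall = 0.0
        for t in np.unique(scores)[::-1]:
            sel = scores >= t
            tp = int(np.sum(labels[sel]))
            fp = int(np.sum(sel) - tp)
            recall = tp / n_pos
            precision = tp / (tp + fp)
            ap += (recall - last_recall) * precision
            last_recall = recall
        res = pr_metrics(labels, scores)
        assert res["average_precision"] == pytest.approx(ap, abs=1e-12)

    def test_max_f1_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=10)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=10), 2)
        best = 0.0
        for t in np.unique(scores):
            pred = scores >= t
            tp = np.sum(pred & (labels == 1))
            if tp == 0:
                continue
            prec = tp / pred.sum()
            rec = tp / labels.sum()
            best = max(best, 2 * prec * rec / (prec + rec))
        assert pr_metrics(labels, scores)["max_f1"] == pytest.approx(best, abs=1e-12)

    def test_youden_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=12)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=12), 2)
        thr = youden(labels, scores)
        pred = scores >= thr
        tpr = np.sum(pred & (labels == 1)) / labels.sum()
        fpr = np.sum(pred & (labels == 0)) / (len(labels) - labels.sum())
        j = tpr - fpr
        best_j = max(
            np.sum((scores >= t) & (labels == 1)) / labels.sum()
            - np.sum((scores >= t) & (labels == 0)) / (len(labels) - labels.sum())
            for t in np.unique(scores)
        )
        assert j == pytest.approx(best_j, abs=1e-12)


class TestConfusionCalibration:
    def test_perfect_predictions_are_identity(self):
        conf, _ = confusion_and_calibration([0, 0, 1, 1], [0.1, 0.2, 0.9, 0.8], 0.5)
        assert np.array_equal(conf, np.eye(2))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=50)
        conf, bins = confusion_and_calibration(labels, scores, 0.5)
        assert np.allclose(conf.sum(axis=1), 1.0)
        assert sum(b["count"] for b in bins) == 50

    def test_calibrated_scores_have_zero_gap(self):
        labels = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        scores = np.array([0.2] * 10 + [0.7] * 10)
        _, bins = confusion_and_calibration(labels, scores, 0.5)
        for b in bins:
            assert b["mean_predicted"] == pytest.approx(b["observed_frequency"])

    def test_pooled_confusion_is_weighted_cluster_sum(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, size=60)
        labels[:4] = [0, 1, 0, 1]
        scores = np.clip(labels * 0.4 + rng.uniform(size=60) * 0.6, 0, 1)
        clusters = rng.integers(1, 4, size=60)
        pooled, _ = confusion_and_calibration(labels, scores, 0.5)
        for row_cls in (0, 1):
            n_row = np.sum(labels == row_cls)
            acc = np.zeros(2)
            for cl in np.unique(clusters):
                mask = clusters == cl
                sub, _ = confusion_and_calibration(labels[mask], scores[mask], 0.5)
                w = np.sum(labels[mask] == row_cls) / n_row
                acc += w * sub[row_cls]
            assert np.allclose(acc, pooled[row_cls], atol=1e-12)

    def test_per_cluster_auc_keys(self):
        labels = np.array([0, 1] * 10)
        scores = np.linspace(0, 1, 20)
        clusters = np.array([1] * 10 + [2] * 10)
        res = per_cluster_auc(labels, scores, clusters)
        assert set(res) == {1, 2}


class TestRegressionMetrics:
    def test_identity_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = regression_metrics(y, y)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        assert res["median_abs_error"] == 0.0

    def test_doubled_prediction_has_slope_two(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        res = regression_metrics(y, 2 * y)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=200)
        pred = 0.7 * y + rng.normal(scale=0.5, size=200)
        res = regression_metrics(y, pred)
        r_direct = (np.mean(y * pred) - y.mean() * pred.mean()) / (y.std() * pred.std())
        assert res["r2"] == pytest.approx(r_direct**2, abs=1e-10)
        slope_direct = np.cov(y, pred)[0, 1] / np.var(y, ddof=1)
        assert res["slope"] == pytest.approx(slope_direct, abs=1e-10)
        assert res["median_abs_error"] == np.median(np.abs(pred - y))

    def test_zero_variance_rejected(self):
        with pytest.raises(MetricError):
            regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class _LinearModel:
    """Linear scorer used as a closed-form attribution oracle."""

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=float).reshape(-1, 1))

    def output(self, t):
        return t @ self.w


class TestIntegratedGradients:
    def test_linear_model_is_exact(self):
        rng = np.random.default_rng(12)
        w = rng.normal(size=30)
        x = rng.normal(size=(3, 30))
        attr = integrated_gradients(_LinearModel(w), x, steps=8)
        assert np.allclose(attr, x * w, atol=1e-10)

    def test_completeness_on_cnn(self):
        model = build_model(ModelSpec(architecture="cnn", seed=13))
        x = np.random.default_rng(13).normal(size=(4, 30))
        attr = integrated_gradients(model, x, steps=256)
        f_x = model.predict(x).scores
        f_0 = model.predict(np.zeros((1, 30))).scores[0]
        for i in range(4):
            diff = f_x[i] - f_0
            assert attr[i].sum() == pytest.approx(diff, rel=0.01, abs=1e-6)

    def test_svm_rejected(self):
        model = build_model(ModelSpec(architecture="svm_rbf"))
        with pytest.raises(CapabilityError):
            integrated_gradients(model, np.zeros((1, 30)))
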