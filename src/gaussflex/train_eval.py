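"""Training protocol and evaluation metrics for flexibility prediction.

Protocol: a stratified holdout split, stratified 5-fold cross-validation on
the remaining pool with early stopping (patience on validation loss), fold
selection by validation accuracy, retraining the selected configuration on
the full pool for its early-stopped epoch budget, and final evaluation on
the untouched holdout.

Metrics: ROC/AUC with a percentile-bootstrap CI, precision-recall / average
precision, maximum F1, the Youden J threshold, row-normalized confusion
matrix, calibration bins, regression statistics (Pearson r, R^2, slope,
median absolute error), and Integrated Gradients attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .autodiff import Tensor, bce_with_logits, mse_loss
from .errors import (
    CapabilityError,
    DataError,
    MetricError,
    ParameterError,
    StratificationError,
)
from .models import ModelSpec, SVMModel, build_model

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the study protocol)."""

    loss: str = "bce"
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 7
    n_folds: int = 5
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("bce", "mse"):
            raise ParameterError(f"unknown loss {self.loss!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ParameterError("holdout_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def holdout_split(n: int, fraction: float, seed: int, stratify_labels=None):
    """Disjoint, exhaustive (train, test) index split with seeded shuffle.

    Test size is ``round(fraction * n)``.  With labels, test membership is
    rounded per class and any remainder is assigned to the largest class.
    """
    if n < 2:
        raise ParameterError("need n >= 2 to split")
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    n_test = int(round(fraction * n))
    if n_test == 0 or n_test == n:
        raise ParameterError(
            f"fraction {fraction} yields an empty side for n={n}"
        )
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    labels = np.asarray(stratify_labels)
    if len(labels) != n:
        raise ParameterError("stratify_labels length mismatch")
    classes, counts = np.unique(labels, return_counts=True)
    per_class = np.round(fraction * counts).astype(int)
    per_class = np.minimum(per_class, counts)
    diff = n_test - per_class.sum()
    largest = int(np.argmax(counts))
    per_class[largest] = int(np.clip(per_class[largest] + diff, 0, counts[largest]))
    test_idx = []
    for cls, take in zip(classes, per_class):
        members = np.nonzero(labels == cls)[0]
        members = rng.permutation(members)
        test_idx.append(members[:take])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


def stratified_kfold(labels, k: int = 5, seed: int = 0):
    """k disjoint validation folds with per-fold class proportions preserved."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[np.argmin(counts)]
        raise StratificationError(
            f"class {small!r} has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(val) for _, val in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _loss_tensor(model, X, y, loss_name):
    if loss_name == "bce":
        return bce_with_logits(model.forward(Tensor(X)), y)
    return mse_loss(model.forward(Tensor(X)), y)


def _eval_loss(model, X, y, loss_name) -> float:
    return float(_loss_tensor(model, X, y, loss_name).data)


def train(model, data, config: TrainConfig, epoch_budget: int | None = None):
    """Minibatch Adam training with early stopping on validation loss.

    ``data`` is ``(X_train, y_train, X_val, y_val)``; ``X_val`` may be None,
    in which case training runs for exactly ``epoch_budget`` (or
    ``config.max_epochs``) epochs with no early stopping.  The best-validation
    weights are restored before returning.

    Returns ``(model, history)`` with per-epoch train/val losses.
    """
    X_tr, y_tr, X_val, y_val = data
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr, dtype=float)
    if len(X_tr) == 0 or (X_val is not None and len(X_val) == 0):
        raise DataError("empty training or validation partition")
    rng = np.random.default_rng(config.seed)
    optimizer = model.make_optimizer(config.lr, config.weight_decay)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_arrays()
    best_epoch = 0
    max_epochs = epoch_budget if epoch_budget is not None else config.max_epochs
    for epoch in range(max_epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            optimizer.zero_grad()
            loss = _loss_tensor(model, X_tr[batch], y_tr[batch], config.loss)
            loss.backward()
            optimizer.step()
        history["train_loss"].append(_eval_loss(model, X_tr, y_tr, config.loss))
        if X_val is not None:
            val = _eval_loss(model, np.asarray(X_val, float), np.asarray(y_val, float),
                             config.loss)
            history["val_loss"].append(val)
            if val < best_val:
                best_val = val
                best_state = model.state_arrays()
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                break
    if X_val is not None:
        model.load_state_arrays(best_state)
        history["best_epoch"] = best_epoch
    else:
        history["best_epoch"] = max_epochs - 1
    return model, history


@dataclass
class CVReport:
    """Per-fold metrics and the configuration selected for retraining."""

    fold_metrics: list
    selected_fold: int
    retrain_epochs: int
    holdout_indices: np.ndarray
    holdout_scores: np.ndarray
    holdout_labels: np.ndarray
    fold_seeds: list = field(default_factory=list)


def _fold_seed(base_seed: int, fold: int) -> int:
    return (base_seed * 131 + fold) % (2**31 - 1)


def cross_validate_then_retrain(X, y, spec: ModelSpec, config: TrainConfig):
    """Full study protocol on one dataset.

    Holds out ``holdout_fraction`` of the data (stratified for
    classification), cross-validates one model per fold, selects the fold
    with the best validation accuracy (classification; lowest validation
    loss for regression; ties to the lowest fold index), re-initializes with
    that fold's seed, retrains on the whole pool for the fold's
    early-stopped epoch count, and scores the untouched holdout.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classify = spec.task == "classification"
    strat = y if classify else None
    pool_idx, hold_idx = holdout_split(
        len(X), config.holdout_fraction, config.seed, stratify_labels=strat
    )
    X_pool, y_pool = X[pool_idx], y[pool_idx]

    if spec.architecture == "svm_rbf":
        # no epochs: fit straight on the pool, score the holdout
        model = build_model(spec).fit(X_pool, y_pool)
        scores = model.predict(X[hold_idx]).scores
        report = CVReport(
            fold_metrics=[], selected_fold=0, retrain_epochs=0,
            holdout_indices=hold_idx, holdout_scores=scores,
            holdout_labels=y[hold_idx],
        )
        return model, report

    if classify:
        folds = stratified_kfold(y_pool, k=config.n_folds, seed=config.seed)
    else:
        kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        folds = [np.sort(val) for _, val in kf.split(X_pool)]

    fold_metrics = []
    fold_seeds = []
    for f, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(len(X_pool)), val_idx)
        seed_f = _fold_seed(config.seed, f)
        fold_seeds.append(seed_f)
        spec_f = ModelSpec(**{**asdict(spec), "seed": seed_f})
        model_f = build_model(spec_f)
        cfg_f = TrainConfig(**{**asdict(config), "seed": seed_f})
        model_f, hist = train(
            model_f,
            (X_pool[tr_idx], y_pool[tr_idx], X_pool[val_idx], y_pool[val_idx]),
            cfg_f,
        )
        val_scores = model_f.predict(X_pool[val_idx]).scores
        if classify:
            acc = float(np.mean((val_scores > 0.5) == (y_pool[val_idx] > 0.5)))
            metric = acc
        else:
            metric = -float(np.min(hist["val_loss"]))
        fold_metrics.append(
            {
                "fold": f,
                "val_metric": metric,
                "best_epoch": int(hist["best_epoch"]),
                "epochs_run": len(hist["train_loss"]),
            }
        )

    best = max(range(len(fold_metrics)), key=lambda f: (fold_metrics[f]["val_metric"], -f))
    budget = fold_metrics[best]["best_epoch"] + 1
    spec_best = ModelSpec(**{**asdict(spec), "seed": fold_seeds[best]})
    cfg_best = TrainConfig(**{**asdict(config), "seed": fold_seeds[best]})
    final_model = build_model(spec_best)
    final_model, _ = train(
        final_model, (X_pool, y_pool, None, None), cfg_best, epoch_budget=budget
    )
    scores = final_model.predict(X[hold_idx]).scores
    report = CVReport(
        fold_metrics=fold_metrics,
        selected_fold=best,
        retrain_epochs=budget,
        holdout_indices=hold_idx,
        holdout_scores=scores,
        holdout_labels=y[hold_idx],
        fold_seeds=fold_seeds,
    )
    return final_model, report


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


def _check_two_classes(labels):
    labels = np.asarray(labels).astype(float)
    if len(np.unique(labels)) != 2:
        raise MetricError("both classes must be present")
    return labels


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def bootstrap_ci(labels, scores, n_boot: int = 2000, seed: int = 0, level: float = 0.95):
    """Percentile-bootstrap confidence interval of the AUC over test indices."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        vals.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def pr_metrics(labels, scores):
    """Average precision plus the maximum F1 with its threshold.

    Returns a dict with ``average_precision``, ``max_f1``, ``f1_threshold``,
    ``f1_precision``, ``f1_recall``.  F1 ties resolve to the lower threshold.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ap = float(average_precision_score(labels, scores))
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # last curve point has no threshold
    p, r = precision[:-1], recall[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    # thresholds ascend; argmax takes the first (lowest) on ties
    best = int(np.argmax(f1))
    return {
        "average_precision": ap,
        "max_f1": float(f1[best]),
        "f1_threshold": float(thresholds[best]),
        "f1_precision": float(p[best]),
        "f1_recall": float(r[best]),
    }


def youden(labels, scores) -> float:
    """Threshold maximizing TPR - FPR with the ``score >= t`` rule.

    Candidates are the observed scores; ties resolve to the lower (more
    sensitive) threshold.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending: first maximum is the lowest t
        pred = scores >= t
        j = (np.sum(pred & (labels == 1)) / n_pos
             - np.sum(pred & (labels == 0)) / n_neg)
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion_and_calibration(labels, scores, threshold: float, n_bins: int = 10):
    """Row-normalized 2x2 confusion at ``threshold`` plus calibration bins.

    Predictions use ``score >= threshold`` (the convention under which the
    Youden threshold realizes its J value).  Calibration uses equal-width
    probability bins; empty bins are omitted.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(float)
    confusion = np.zeros((2, 2))
    for true_cls in (0, 1):
        mask = labels == true_cls
        if mask.sum() == 0:
            continue
        for pred_cls in (0, 1):
            confusion[true_cls, pred_cls] = np.mean(pred[mask] == pred_cls)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (scores >= lo) & (scores < hi if b < n_bins - 1 else scores <= hi)
        if mask.sum() == 0:
            continue
        bins.append(
            {
                "mean_predicted": float(scores[mask].mean()),
                "observed_frequency": float(labels[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return confusion, bins


def per_cluster_auc(labels, scores, clusters) -> dict:
    """AUC within each cluster (clusters with one class yield NaN)."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(clusters)
    out = {}
    for cl in np.unique(clusters):
        mask = clusters == cl
        if len(np.unique(labels[mask])) < 2:
            out[int(cl)] = float("nan")
        else:
            out[int(cl)] = float(roc_auc_score(labels[mask], scores[mask]))
    return out


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------


def regression_metrics(y_true, y_pred) -> dict:
    """Pearson r, R^2 (= r^2), least-squares slope of predicted on true,
    and the median absolute error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 3 or y_true.shape != y_pred.shape:
        raise MetricError("need >= 3 paired values")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise MetricError("zero variance in inputs")
    r = float(_stats.pearsonr(y_true, y_pred).statistic)
    slope = float(np.polyfit(y_true, y_pred, 1)[0])
    return {
        "pearson_r": r,
        "r2": r**2,
        "slope": slope,
        "median_abs_error": float(np.median(np.abs(y_pred - y_true))),
    }


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------


def integrated_gradients(model, inputs, baseline=None, steps: int = 256) -> np.ndarray:
    """Integrated Gradients along the straight path from baseline to input.

    The path integral is Riemann-approximated at ``steps`` midpoints; the
    completeness axiom (attributions sum to ``model(x) - model(baseline)``)
    then holds up to discretization error.  Differentiates the task-scaled
    output (probability for classification).
    """
    if isinstance(model, SVMModel):
        raise CapabilityError("Integrated Gradients needs a differentiable model")
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if baseline is None:
        baseline = np.zeros(X.shape[1])
    baseline = np.asarray(baseline, dtype=float)
    alphas = (np.arange(steps) + 0.5) / steps
    total = np.zeros_like(X)
    for alpha in alphas:
        pts = baseline[None, :] + alpha * (X - baseline[None, :])
        t = Tensor(pts, requires_grad=True)
        out = model.output(t)
        out.sum().backward()
        total += t.grad
    return (X - baseline[None, :]) * total / steps


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Bundle of the evaluation metrics for one model run."""

    auc: float | None = None
    auc_ci: tuple | None = None
    average_precision: float | None = None
    max_f1: float | None = None
    f1_precision: float | None = None
    f1_recall: float | None = None
    youden_threshold: float | None = None
    confusion: np.ndarray | None = None
    calibration: list | None = None
    per_cluster_auc: dict | None = None
    regression: dict | None = None
    attributions: np.ndarray | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, np.ndarray):
                val = val.tolist()
            out[key] = val
        return out


def evaluate_classifier(
    labels, scores, clusters=None, model=None, inputs=None,
    n_boot: int = 2000, seed: int = 0,
) -> EvalReport:
    """Assemble the full classification report from holdout labels and scores."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    auc = roc_auc(labels, scores)
    ci = bootstrap_ci(labels, scores, n_boot=n_boot, seed=seed)
    pr = pr_metrics(labels, scores)
    thr = youden(labels, scores)
    confusion, calibration = confusion_and_calibration(labels, scores, thr)
    report = EvalReport(
        auc=auc,
        auc_ci=ci,
        average_precision=pr["average_precision"],
        max_f1=pr["max_f1"],
        f1_precision=pr["f1_precision"],
        f1_recall=pr["f1_recall"],
        youden_threshold=thr,
        confusion=confusion,
        calibration=calibration,
        seed=seed,
    )
    if clusters is not None:
        report.per_cluster_auc = per_cluster_auc(labels, scores, clusters)
    if model is not None and inputs is not None and not isinstance(model, SVMModel):
        report.attributions = np.abs(
            integrated_gradients(model, inputs)
        ).mean(axis=0)
    return report


def evaluate_regressor(y_true, y_pred, clusters=None, seed: int = 0) -> EvalReport:
    """Assemble the regression report, optionally per cluster."""
    report = EvalReport(regression=regression_metrics(y_true, y_pred), seed=seed)
    if clusters is not None:
        clusters = np.asarray(clusters)
        per_cluster = {}
        for cl in np.unique(clusters):
            mask = clusters == cl
            try:
                per_cluster[int(cl)] = regression_metrics(
                    np.asarray(y_true)[mask], np.asarray(y_pred)[mask]
                )
            except MetricError:
                per_cluster[int(cl)] = None
        report.regression["per_cluster"] = per_cluster
    return report
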