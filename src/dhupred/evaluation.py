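"""Evaluation metrics, ROC/AUC, repeated k-fold CV and independent testing.

The metric set follows the field's convention for modification-site
predictors: sensitivity Sn = 1 - FN/N+, specificity Sp = 1 - FP/N-, overall
accuracy Acc, the Matthews correlation coefficient, precision, F1 and the
area under the ROC curve.  N+ and N- denote the positive (true D-site) and
negative totals, FN (N-+) positives predicted negative and FP (N+-)
negatives predicted positive.

AUC is computed by the trapezoid rule over the empirical ROC curve, which is
equal to the Mann-Whitney pair-ordering statistic with ties counted one half
(the property-test suite holds the two routes to each other).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, KFold

from .encoders import FeatureMatrix
from .models import ModelSpec, TrainedModel, fit, predict_labels, predict_scores
from .resample import OversampleSpec, oversample_indices, assert_no_leakage, LeakageError

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCCurve",
    "CVResult",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "evaluate_predictions",
    "cross_validate",
    "independent_test",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """The four counts of a binary confusion table.

    ``n_pos``/``n_neg`` are the class totals; ``fn`` the positives predicted
    negative; ``fp`` the negatives predicted positive.
    """

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.fn > self.n_pos or self.fp > self.n_neg:
            raise ValueError("errors cannot exceed class totals")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Acc, MCC, precision, F1 and (when scores exist) AUC."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    precision: float
    F1: float
    AUC: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1), both non-decreasing."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]

    def to_tsv(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as out:
            out.write("fpr\ttpr\n")
            for x, y in zip(self.fpr, self.tpr):
                out.write(f"{float(x)!r}\t{float(y)!r}\n")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the confusion table for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    return ConfusionCounts(n_pos, n_neg, fn, fp)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("%s denominator is zero; reporting 0", what)
        return 0.0
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from a confusion table (AUC requires scores).

    Sn = 1 - FN/N+, Sp = 1 - FP/N-, Acc = 1 - (FN+FP)/(N+ + N-); MCC is the
    classical correlation form; a zero denominator in MCC or precision gives
    0 with a logged warning.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("Sn/Sp undefined: both classes must be present")
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / c.total
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, denom, "MCC")
    precision = _safe_div(tp, tp + fp, "precision")
    f1 = _safe_div(2 * precision * sn, precision + sn, "F1")
    return MetricSet(Sn=sn, Sp=sp, Acc=acc, MCC=mcc, precision=precision, F1=f1)


def roc_auc(y_true, scores) -> tuple[ROCCurve, float]:
    """ROC curve by threshold sweep and its trapezoid-rule AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(tuple(fpr.tolist()), tuple(tpr.tolist())), auc


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricSet:
    """Full metric set (including AUC) from true labels and scores."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    base = metrics_from_confusion(confusion(y_true, y_pred))
    _, auc = roc_auc(y_true, scores)
    return MetricSet(**{**base.to_dict(), "AUC": auc})


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics of a repeated k-fold cross-validation.

    ``folds`` holds one entry per (repeat, fold); ``assignments`` records the
    test indices of each fold so any run can be replayed; ``seeds`` are the
    per-repeat shuffle seeds (seed + repeat index).
    """

    folds: tuple[dict, ...]
    k: int
    repeats: int
    seeds: tuple[int, ...]
    assignments: tuple[tuple[int, ...], ...]

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([f["metrics"].to_dict()[name] for f in self.folds])

    def mean(self, name: str) -> float:
        return float(self.metric_values(name).mean())

    def std(self, name: str) -> float:
        return float(self.metric_values(name).std(ddof=1))

    def summary(self) -> dict:
        out = {}
        for name in ("Sn", "Sp", "Acc", "MCC", "precision", "F1", "AUC"):
            vals = self.metric_values(name)
            out[name] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=1))}
        return out


def cross_validate(
    X,
    y,
    spec: ModelSpec,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    oversample: OversampleSpec | None = None,
    stratified: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation with fold-internal oversampling.

    Each repeat r shuffles the samples with seed ``seed + r`` into k folds
    (stratified by class by default); each fold is scored by a model trained
    on the remaining folds.  When an oversample spec is given, positive
    duplication happens inside each training fold only — the tested fold is
    never expanded.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes")
    if stratified and counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k={k}; reduce k"
        )
    folds: list[dict] = []
    assignments: list[tuple[int, ...]] = []
    seeds = tuple(seed + r for r in range(repeats))
    for r, rep_seed in enumerate(seeds):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=k, shuffle=True, random_state=rep_seed)
        for f, (train_idx, test_idx) in enumerate(splitter.split(Xv, y)):
            if oversample is not None:
                local = OversampleSpec(
                    passes=oversample.passes,
                    p=oversample.p,
                    seed=oversample.seed + 1000 * r + f,
                )
                rows = oversample_indices(y[train_idx], local)
                fit_idx = train_idx[rows]
            else:
                fit_idx = train_idx
            if len(np.unique(y[fit_idx])) < 2:
                raise ValueError(
                    f"repeat {r} fold {f}: a class is absent from the training "
                    "fold; enable stratification"
                )
            trained = fit(spec, Xv[fit_idx], y[fit_idx])
            scores = predict_scores(trained, Xv[test_idx])
            metrics = evaluate_predictions(y[test_idx], scores)
            folds.append(
                {"repeat": r, "fold": f, "metrics": metrics,
                 "n_test": int(len(test_idx))}
            )
            assignments.append(tuple(int(i) for i in test_idx))
    return CVResult(tuple(folds), k, repeats, seeds, tuple(assignments))


def independent_test(
    trained: TrainedModel, X_test, y_test, test_ids=None
) -> MetricSet:
    """Score a trained model on held-out data, guarding against leakage.

    When both the model's recorded training ids and the test ids are
    available, any overlap (after stripping oversampling provenance) raises.
    """
    if test_ids is None and isinstance(X_test, FeatureMatrix):
        test_ids = X_test.sample_ids
    if trained.train_ids is not None and test_ids is not None:
        assert_no_leakage(trained.train_ids, test_ids)
    scores = predict_scores(trained, X_test)
    return evaluate_predictions(np.asarray(y_test, dtype=int), scores)
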