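"""Logistic-regression classifier, k-fold cross-validation and metrics.

The classifier is plain (effectively unregularised) logistic
regression; folds are stratified and shuffled under a stated seed.
Aggregate accuracy/precision/recall/F1 average the per-fold metrics;
AUC is reported both pooled over held-out probabilities (headline) and
as the per-fold average, since averaging a rank statistic over
few-subject folds is unstable.

Undefined metrics (e.g. precision in a fold with no positive calls)
are flagged, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConvergenceError, SpecError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise SpecError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy, precision, recall, F1; None where the denominator is 0."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """accuracy=(TP+TN)/n, recall=TP/(TP+FN), precision=TP/(TP+FP),
    F1=2TP/(2TP+FP+FN); any zero denominator flags that metric undefined."""
    if c.total == 0:
        raise SpecError("empty confusion matrix")
    undefined = []
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, undefined = None, undefined + ["precision"]
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, undefined = None, undefined + ["recall"]
    if 2 * c.tp + c.fp + c.fn > 0:
        f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    else:
        f1, undefined = None, undefined + ["f1"]
    return Metrics(accuracy, precision, recall, f1, tuple(undefined))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score of a random positive > random negative),
    ties counted one half — the Mann–Whitney statistic over n1·n0."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise SpecError("roc_auc needs both classes present")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-8, max_iter: int = 5000
) -> LogisticRegression:
    """Fit a plain logistic model (tiny ridge for numerical stability only).

    Raises :class:`ConvergenceError` with iteration diagnostics if the
    optimiser exhausts its budget.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise SpecError("both classes must be present in y_train")
    model = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-8
    )
    model.fit(np.asarray(X, dtype=float), y)
    n_iter = int(np.max(model.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"logistic fit used all {n_iter}/{max_iter} iterations without "
            "meeting tolerance"
        )
    return model


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    stratified: bool = True
    seed: int = 0

    def validate(self, n: int, y: np.ndarray | None = None) -> None:
        if not 2 <= self.k <= n:
            raise SpecError(f"k={self.k} invalid for n={n}")


@dataclass
class CVResult:
    """Per-fold confusion counts/metrics and their aggregates."""

    k: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[Metrics]
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float  # pooled held-out probabilities (headline)
    auc_fold_mean: float | None  # average of per-fold AUCs, where defined
    pooled_counts: ConfusionCounts = field(default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "auc_fold_mean": self.auc_fold_mean,
            "pooled_counts": {
                "tp": self.pooled_counts.tp,
                "fp": self.pooled_counts.fp,
                "tn": self.pooled_counts.tn,
                "fn": self.pooled_counts.fn,
            },
            "folds": [
                {
                    "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
                for c, m in zip(self.fold_counts, self.fold_metrics)
            ],
        }


def format_results_table(rows: list[dict]) -> str:
    """Plain-text summary table: one row per (setting, method) with the
    five metrics and the selected-subset size."""
    cols = ("setting", "method", "k", "accuracy", "precision", "recall",
            "f1", "auc", "n_features")
    lines = []
    table = [[str(r.get(c, "-")) if not isinstance(r.get(c), float)
              else f"{r[c]:.3f}" for c in cols] for r in rows]
    widths = [max(len(c), *(len(t[i]) for t in table)) if table else len(c)
              for i, c in enumerate(cols)]
    lines.append("  ".join(c.ljust(w) for c, w in zip(cols, widths)))
    lines.append("  ".join("-" * w for w in widths))
    for t in table:
        lines.append("  ".join(v.ljust(w) for v, w in zip(t, widths)))
    return "\n".join(lines)


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None and not isnan(v)]
    return float(np.mean(defined)) if defined else None


def _folds(y: np.ndarray, cfg: CVConfig):
    classes, counts = np.unique(y, return_counts=True)
    if cfg.stratified and len(classes) == 2 and counts.min() >= cfg.k:
        kf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    else:
        kf = KFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    return kf.split(np.zeros(len(y)), y)


def kfold_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    cfg: CVConfig = CVConfig(),
) -> CVResult:
    """Stratified k-fold evaluation of logistic regression on masked columns.

    Every subject is held out exactly once; per-fold metrics are
    averaged (skipping flagged-undefined folds) and AUC is additionally
    pooled across all held-out probabilities.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cfg.validate(len(y), y)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SpecError("feature mask is empty")
        X = X[:, mask]

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[Metrics] = []
    fold_aucs: list[float] = []
    pooled_scores = np.empty(len(y))
    pooled_true = np.empty(len(y), dtype=int)
    pos = 0
    for train_idx, test_idx in _folds(y, cfg):
        model = fit_logistic(X[train_idx], y[train_idx])
        prob = model.predict_proba(X[test_idx])[:, list(model.classes_).index(1)]
        pred = (prob >= 0.5).astype(int)
        c = ConfusionCounts.from_predictions(y[test_idx], pred)
        fold_counts.append(c)
        fold_metrics.append(confusion_metrics(c))
        if len(np.unique(y[test_idx])) == 2:
            fold_aucs.append(roc_auc(prob, y[test_idx]))
        pooled_scores[pos : pos + len(test_idx)] = prob
        pooled_true[pos : pos + len(test_idx)] = y[test_idx]
        pos += len(test_idx)
    assert pos == len(y), "folds must partition the cohort"

    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    return CVResult(
        k=cfg.k,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        precision=_mean_defined([m.precision for m in fold_metrics]),
        recall=_mean_defined([m.recall for m in fold_metrics]),
        f1=_mean_defined([m.f1 for m in fold_metrics]),
        auc=roc_auc(pooled_scores, pooled_true),
        auc_fold_mean=float(np.mean(fold_aucs)) if fold_aucs else None,
        pooled_counts=pooled,
    )
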