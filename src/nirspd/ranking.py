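"""Feature-ranking filters, embedded selectors and the ensemble vote.

Five rankers/selectors feed the ensemble stage: three classifier-free
filters (mean absolute difference, mutual information gain, Fisher
score) whose top-p% sets are combined by a two-of-three vote swept over
p = 1..10 %, plus two embedded sparse linear selectors (elastic-net
logistic regression and L1-norm linear SVM).  The vote winner and the
two embedded subsets are combined by set union into the candidate
universe for the second-stage subset search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import LinearSVC

from .exceptions import ConvergenceError, SpecError


@dataclass
class RankingResult:
    """Per-feature scores of one ranking method and the induced top sets."""

    method: str
    scores: np.ndarray
    removed: np.ndarray | None = None  # e.g. zero-MAD features

    @property
    def order(self) -> np.ndarray:
        """Feature indices by descending score; ties by ascending index."""
        d = self.scores.size
        return np.lexsort((np.arange(d), -self.scores))

    def top_p_set(self, p: float) -> np.ndarray:
        """Indices of the top ⌈p·d/100⌉ features (ceiling keeps p=1 non-empty)."""
        if not 0 < p <= 100:
            raise SpecError("p must be in (0, 100]")
        k = math.ceil(p * self.scores.size / 100.0)
        return np.sort(self.order[:k])


@dataclass
class FeatureSubset:
    """Boolean mask over feature columns plus provenance of its origin."""

    mask: np.ndarray
    provenance: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def union(self, other: "FeatureSubset", provenance: str | None = None) -> "FeatureSubset":
        if self.mask.size != other.mask.size:
            raise SpecError("subsets live over different feature universes")
        return FeatureSubset(
            self.mask | other.mask,
            provenance or f"union({self.provenance},{other.provenance})",
        )


def _as_array(X) -> np.ndarray:
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim != 2:
        raise SpecError("feature matrix must be 2-D")
    return X


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise SpecError("both classes must be present")
    return y


def mad_scores(X) -> RankingResult:
    """Mean absolute difference from the column mean; zero-MAD features
    carry no information and are flagged removed."""
    X = _as_array(X)
    if X.shape[0] < 2:
        raise SpecError("need at least 2 rows")
    scores = np.abs(X - X.mean(axis=0)).mean(axis=0)
    return RankingResult("mad", scores, removed=scores == 0)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise by quantile edges; duplicate edges collapse bins."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def mig_scores(X, y, n_bins: int | None = None, estimator: str = "discretized") -> RankingResult:
    """Mutual information (bits) between each feature and the class label.

    Default estimator: equal-frequency discretisation into
    ``min(10, n//4)`` bins and the plug-in formula — invariant to any
    strictly monotone feature transform.  ``estimator='knn'`` switches
    to scikit-learn's neighbour-based continuous estimator (nats
    rescaled to bits).
    """
    X = _as_array(X)
    y = _check_binary(y)
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise SpecError("need at least 2 rows per class")
    if estimator == "knn":
        from sklearn.feature_selection import mutual_info_classif

        mi = mutual_info_classif(X, y, random_state=0) / math.log(2)
        return RankingResult("mig", mi)
    if estimator != "discretized":
        raise SpecError(f"unknown MIG estimator {estimator!r}")
    n_bins = n_bins or min(10, max(2, n // 4))
    py = counts / n
    hy = -np.sum(py * np.log2(py))
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        b = _equal_frequency_bins(X[:, j], n_bins)
        # H(y) - H(y|bin)
        h_cond = 0.0
        for bv in np.unique(b):
            sel = b == bv
            pb = sel.mean()
            for c in classes:
                p = (y[sel] == c).mean()
                if p > 0:
                    h_cond -= pb * p * np.log2(p)
        scores[j] = max(0.0, hy - h_cond)
    return RankingResult("mig", scores)


def fisher_scores(X, y) -> RankingResult:
    """Ratio of (class-size-weighted) between-class variance to pooled
    within-class variance, per feature; 0/0 is defined as 0 and x/0 as
    +inf so a perfectly separated feature ranks first."""
    X = _as_array(X)
    y = _check_binary(y)
    n = len(y)
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in np.unique(y):
        sel = y == c
        w = sel.sum() / n
        mc = X[sel].mean(axis=0)
        between += w * (mc - mu) ** 2
        within += w * X[sel].var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            within > 0, between / np.where(within > 0, within, 1.0),
            np.where(between > 0, np.inf, 0.0),
        )
    return RankingResult("fisher", scores)


_DEFAULT_C_GRID = (0.01, 0.1, 1.0)


def _nonzero_mask(coefs: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    return np.abs(coefs).ravel() > tol


def _inner_folds(y: np.ndarray, cv: int, seed: int) -> StratifiedKFold:
    counts = np.bincount(y)
    k = int(min(cv, counts[counts > 0].min()))
    if k < 2:
        raise SpecError("need at least 2 rows per class for the internal CV grid")
    return StratifiedKFold(k, shuffle=True, random_state=seed)


def _fit_converged(model, X: np.ndarray, y: np.ndarray, what: str):
    """Fit, retrying once with a 4x iteration budget; raise with
    diagnostics if the optimiser still exhausts it."""
    model.fit(X, y)
    n_iter = int(np.max(model.n_iter_))
    if n_iter >= model.max_iter:
        model.set_params(max_iter=model.max_iter * 4)
        model.fit(X, y)
        n_iter = int(np.max(model.n_iter_))
        if n_iter >= model.max_iter:
            raise ConvergenceError(
                f"{what} fit used all {n_iter}/{model.max_iter} iterations "
                "without meeting tolerance"
            )
    return model


def elastic_net_subset(
    X,
    y,
    penalty_strength: float | None = None,
    l1_ratio: float = 0.5,
    cv: int = 5,
    seed: int = 0,
) -> FeatureSubset:
    """Features with nonzero coefficients of elastic-net-penalised
    logistic regression.

    ``penalty_strength`` is the inverse of scikit-learn's ``C``; when
    None it is chosen by an internal stratified 5-fold accuracy grid.
    Expects standardized columns.
    """
    X = _as_array(X)
    y = _check_binary(y)

    def make(c: float) -> LogisticRegression:
        return LogisticRegression(
            solver="saga", l1_ratio=l1_ratio,
            C=c, max_iter=3000, tol=1e-4, random_state=seed,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalty_strength is None:
            gs = GridSearchCV(
                make(1.0), {"C": list(_DEFAULT_C_GRID)},
                cv=_inner_folds(y, cv, seed),
                scoring="accuracy", refit=False,
            )
            gs.fit(X, y)
            model = make(gs.best_params_["C"])
        else:
            if penalty_strength < 0:
                raise SpecError("penalty_strength must be >= 0")
            c = np.inf if penalty_strength == 0 else 1.0 / penalty_strength
            model = make(min(c, 1e10))
        model = _fit_converged(model, X, y, "elastic-net")
    return FeatureSubset(_nonzero_mask(model.coef_), "elastic_net")


def l1_svm_subset(
    X, y, penalty_strength: float | None = None, cv: int = 5, seed: int = 0
) -> FeatureSubset:
    """Features with nonzero coefficients of an L1-penalised linear SVM
    (hinge-family squared loss, primal).  Interface mirrors
    :func:`elastic_net_subset`."""
    X = _as_array(X)
    y = _check_binary(y)

    def make(c: float) -> LinearSVC:
        return LinearSVC(penalty="l1", dual=False, C=c, max_iter=20000, tol=1e-5)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalty_strength is None:
            gs = GridSearchCV(
                make(1.0), {"C": list(_DEFAULT_C_GRID)},
                cv=_inner_folds(y, cv, seed),
                scoring="accuracy", refit=False,
            )
            gs.fit(X, y)
            model = make(gs.best_params_["C"])
        else:
            if penalty_strength < 0:
                raise SpecError("penalty_strength must be >= 0")
            c = np.inf if penalty_strength == 0 else 1.0 / penalty_strength
            model = make(min(c, 1e10))
        model = _fit_converged(model, X, y, "L1-SVM")
    return FeatureSubset(_nonzero_mask(model.coef_), "l1_svm")


def vote_subset(filters: Sequence[RankingResult], p: float) -> FeatureSubset:
    """Features placed in the top p% by at least two of the three filters."""
    if len(filters) != 3:
        raise SpecError("the vote takes exactly three filter rankings")
    d = filters[0].scores.size
    if any(f.scores.size != d for f in filters):
        raise SpecError("filters rank different feature sets")
    votes = np.zeros(d, dtype=int)
    for f in filters:
        votes[f.top_p_set(p)] += 1
    return FeatureSubset(votes >= 2, f"vote_2of3_top{p}pct")


def vote_sweep(
    X,
    y,
    filters: Sequence[RankingResult],
    evaluator: Callable[[np.ndarray], float],
    percents: Sequence[float] = tuple(range(1, 11)),
) -> tuple[FeatureSubset, list[dict]]:
    """Sweep the two-of-three vote over p = 1..10 % and keep the most
    accurate subset.

    ``evaluator`` maps a boolean mask to a (cross-validated) accuracy.
    Ties prefer the smaller subset, then the smaller p.  Empty subsets
    are recorded with undefined accuracy and skipped.
    """
    table: list[dict] = []
    best: tuple[float, int, float] | None = None  # (-acc, size, p) minimised
    best_subset: FeatureSubset | None = None
    for p in percents:
        subset = vote_subset(filters, p)
        if subset.size == 0:
            table.append({"p": p, "size": 0, "accuracy": None})
            continue
        acc = float(evaluator(subset.mask))
        table.append({"p": p, "size": subset.size, "accuracy": acc})
        key = (-acc, subset.size, p)
        if best is None or key < best:
            best, best_subset = key, subset
    if best_subset is None:
        raise SpecError("every swept subset was empty")
    return best_subset, table


def ensemble_combine(*subsets: FeatureSubset) -> FeatureSubset:
    """Union of the selection strategies' subsets (the ensemble keeps any
    feature at least one strategy trusts)."""
    if not subsets:
        raise SpecError("nothing to combine")
    out = subsets[0]
    for s in subsets[1:]:
        out = out.union(s)
    return FeatureSubset(out.mask, "ensemble_union")
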