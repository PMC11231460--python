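"""Filter scores, embedded selectors, the two-of-three vote and its sweep."""

import numpy as np
import pytest

from nirspd.exceptions import SpecError
from nirspd.ranking import (
    FeatureSubset,
    elastic_net_subset,
    ensemble_combine,
    fisher_scores,
    l1_svm_subset,
    mad_scores,
    mig_scores,
    vote_subset,
    vote_sweep,
)
from conftest import make_planted


def _balanced_labels(n):
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    return y


class TestMadScores:
    def test_hand_example(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        assert mad_scores(X).scores[0] == 1.0

    def test_constant_column_flagged_removed(self):
        X = np.c_[np.full(6, 2.0), np.arange(6.0)]
        r = mad_scores(X)
        assert r.scores[0] == 0.0 and r.removed[0]
        assert not r.removed[1]

    def test_positive_scaling_homogeneity(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        r1, r2 = mad_scores(X), mad_scores(3.0 * X)
        assert np.allclose(r2.scores, 3.0 * r1.scores)
        assert np.array_equal(r1.order, r2.order)

    def test_shift_invariance(self):
        X = np.random.default_rng(1).normal(size=(15, 4))
        assert np.allclose(mad_scores(X).scores, mad_scores(X + 7.0).scores)


class TestMigScores:
    def test_feature_equal_to_label_is_one_bit(self):
        y = _balanced_labels(40)
        assert mig_scores(y.reshape(-1, 1).astype(float), y).scores[0] == pytest.approx(1.0)

    def test_independent_feature_within_permutation_null(self):
        rng = np.random.default_rng(2)
        y = _balanced_labels(40)
        x = rng.normal(size=(40, 1))
        observed = mig_scores(x, y).scores[0]
        null = []
        for _ in range(200):
            null.append(mig_scores(x, rng.permutation(y)).scores[0])
        assert observed <= np.quantile(null, 0.975)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = _balanced_labels(30)
        x = rng.normal(size=(30, 1))
        a = mig_scores(x, y).scores[0]
        b = mig_scores(np.exp(x), y).scores[0]
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(SpecError):
            mig_scores(np.zeros((10, 1)), np.zeros(10, dtype=int))


class TestFisherScores:
    def test_six_row_formula_oracle(self):
        X = np.array([[1.0], [2.0], [3.0], [6.0], [7.0], [8.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        mu = X.mean()
        between = sum(
            (y == c).mean() * (X[y == c].mean() - mu) ** 2 for c in (0, 1)
        )
        within = sum((y == c).mean() * X[y == c].var() for c in (0, 1))
        assert fisher_scores(X, y).scores[0] == pytest.approx(between / within)

    def test_null_scores_are_small(self):
        """Null Fisher scores scale like chi-square(1)/n; at n=40 the bulk
        sits below 0.1."""
        rng = np.random.default_rng(4)
        y = _balanced_labels(40)
        scores = [
            fisher_scores(rng.normal(size=(40, 1)), rng.permutation(y)).scores[0]
            for _ in range(200)
        ]
        assert np.mean(np.array(scores) < 0.1) >= 0.9
        assert np.median(scores) < 0.05

    def test_perfect_separation_ranks_first(self):
        X = np.c_[np.r_[-np.ones(5), np.ones(5)],
                  np.random.default_rng(5).normal(size=10)]
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        r = fisher_scores(X, y)
        assert np.isinf(r.scores[0])
        assert r.order[0] == 0

    def test_shift_invariance(self):
        X, y, _ = make_planted(seed=6)
        assert np.allclose(
            fisher_scores(X, y).scores, fisher_scores(X + 100.0, y).scores
        )


class TestEmbeddedSelectors:
    def test_infinite_penalty_empty_subset(self):
        X, y, _ = make_planted(n=30, d=10, seed=7, standardized=True)
        assert elastic_net_subset(X, y, penalty_strength=1e8).size == 0
        assert l1_svm_subset(X, y, penalty_strength=1e8).size <= 1

    def test_zero_penalty_selects_everything(self):
        X, y, _ = make_planted(n=30, d=5, seed=8, standardized=True)
        assert elastic_net_subset(X, y, penalty_strength=0.0).size == 5

    @pytest.mark.parametrize("selector", [elastic_net_subset, l1_svm_subset])
    def test_planted_feature_recovered(self, selector):
        hits = 0
        runs = 100
        for s in range(runs):
            rng = np.random.default_rng(s)
            y = _balanced_labels(60)
            X = rng.normal(size=(60, 20))
            X[:, 3] = y + 0.1 * rng.normal(size=60)
            X = (X - X.mean(0)) / X.std(0)
            subset = selector(X, y, penalty_strength=1.0)
            hits += bool(subset.mask[3])
        assert hits >= 95

    def test_redundant_duplicate_kept_sparse(self):
        rng = np.random.default_rng(9)
        y = _balanced_labels(40)
        X = np.c_[y + 0.05 * rng.normal(size=40),
                  y + 0.05 * rng.normal(size=40),
                  rng.normal(size=40)]
        X = (X - X.mean(0)) / X.std(0)
        assert l1_svm_subset(X, y, penalty_strength=2.0).size <= 2


class TestVote:
    def _rankings(self, d, seed=0):
        rng = np.random.default_rng(seed)
        from nirspd.ranking import RankingResult

        return [RankingResult(f"m{i}", rng.random(d)) for i in range(3)]

    def test_top_set_size_ceiling(self):
        r = self._rankings(792)[0]
        assert r.top_p_set(1).size == 8  # ceil(7.92)

    def test_unanimous_top_feature_always_included(self):
        from nirspd.ranking import RankingResult

        d = 50
        filters = []
        rng = np.random.default_rng(1)
        for i in range(3):
            s = rng.random(d)
            s[17] = 2.0  # everyone's #1
            filters.append(RankingResult(f"m{i}", s))
        for p in range(1, 11):
            assert vote_subset(filters, p).mask[17]

    def test_single_filter_support_excluded(self):
        from nirspd.ranking import RankingResult

        d = 100
        base = np.linspace(1, 0, d)
        f1 = RankingResult("a", base.copy())
        s2 = base.copy()
        s2[0], s2[99] = 0.0, 2.0  # feature 99 is #1 only for this filter
        f2 = RankingResult("b", s2)
        f3 = RankingResult("c", base.copy())
        sub = vote_subset([f1, f2, f3], 1)
        assert not sub.mask[99]

    def test_nested_in_p(self):
        filters = self._rankings(200, seed=2)
        prev = vote_subset(filters, 1).mask
        for p in range(2, 11):
            cur = vote_subset(filters, p).mask
            assert np.all(prev <= cur)
            prev = cur

    def test_sweep_returns_ten_candidates_and_recovers_planted(self):
        X, y, informative = make_planted(n=40, d=100, seed=10)
        filters = [mad_scores(X), mig_scores(X, y), fisher_scores(X, y)]
        from nirspd.subset_search import make_cv_evaluator

        best, table = vote_sweep(X, y, filters, make_cv_evaluator(X, y, seed=0))
        assert len(table) == 10
        assert best.mask[informative].any()


class TestEnsembleCombine:
    def test_union_of_disjoint_sizes(self):
        d = 20
        masks = [np.zeros(d, bool) for _ in range(3)]
        masks[0][:3] = True
        masks[1][3:7] = True
        masks[2][7:12] = True
        subs = [FeatureSubset(m, f"s{i}") for i, m in enumerate(masks)]
        assert ensemble_combine(*subs).size == 12

    def test_idempotent_on_identical_subsets(self):
        m = np.zeros(10, bool)
        m[[1, 4]] = True
        out = ensemble_combine(FeatureSubset(m, "a"), FeatureSubset(m, "b"))
        assert np.array_equal(out.mask, m)

    def test_every_input_is_subset_of_union(self):
        rng = np.random.default_rng(11)
        subs = [FeatureSubset(rng.random(30) < 0.3, f"s{i}") for i in range(3)]
        out = ensemble_combine(*subs)
        for s in subs:
            assert np.all(s.mask <= out.mask)


def test_rankers_invariant_to_row_order():
    X, y, _ = make_planted(seed=12)
    perm = np.random.default_rng(12).permutation(len(y))
    for fn in (lambda a, b: mad_scores(a), mig_scores, fisher_scores):
        assert np.allclose(fn(X, y).scores, fn(X[perm], y[perm]).scores)


def test_rankers_place_planted_features_in_top_decile():
    """All five selection methods should concentrate planted signal in
    their top 10% on moderately separated data."""
    runs, need = 30, 27  # >= 90%
    counts = {"mad": 0, "mig": 0, "fisher": 0, "enet": 0, "svm": 0}
    for s in range(runs):
        X, y, informative = make_planted(n=40, d=100, n_informative=5,
                                         effect=2.0, seed=100 + s)
        top_k = 10
        for name, ranker in (("mad", lambda: mad_scores(X)),
                             ("mig", lambda: mig_scores(X, y)),
                             ("fisher", lambda: fisher_scores(X, y))):
            top = ranker().order[:top_k]
            counts[name] += np.isin(informative, top).sum() >= 3
        Xs = (X - X.mean(0)) / X.std(0)
        counts["enet"] += elastic_net_subset(Xs, y, penalty_strength=1.0).mask[
            informative].sum() >= 3
        counts["svm"] += l1_svm_subset(Xs, y, penalty_strength=1.0).mask[
            informative].sum() >= 3
    for name, c in counts.items():
        assert c >= need, f"{name} recovered planted features in only {c}/{runs} runs"
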