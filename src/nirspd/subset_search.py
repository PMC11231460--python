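"""Second-stage subset selection: greedy wrappers, a genetic algorithm,
and an exhaustive oracle for small problems.

All searches share one evaluator interface — a callable mapping a
boolean feature mask to a fitness (by default the mean stratified
k-fold cross-validated accuracy of logistic regression on the masked
columns).  The empty mask has fitness 0 by convention.  Every search is
deterministic given (data, config, seed); fitness values are cached by
mask so duplicate candidates cost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import SpecError
from .model_eval import CVConfig, kfold_evaluate
from .ranking import FeatureSubset

Evaluator = Callable[[np.ndarray], float]


def evaluate_subset(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, k: int = 5, seed: int = 0
) -> float:
    """Mean k-fold CV accuracy of logistic regression on the masked columns;
    0 for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return kfold_evaluate(X, y, mask, CVConfig(k=k, seed=seed)).accuracy


class CachedEvaluator:
    """Memoising wrapper; the cache changes cost, never results."""

    def __init__(self, fn: Evaluator):
        self._fn = fn
        self.cache: dict[bytes, float] = {}
        self.calls = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = mask.tobytes()
        if key not in self.cache:
            self.calls += 1
            self.cache[key] = float(self._fn(mask))
        return self.cache[key]


def make_cv_evaluator(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0, cache: bool = True
) -> Evaluator:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)

    def fn(mask: np.ndarray) -> float:
        return evaluate_subset(X, y, mask, k=k, seed=seed)

    return CachedEvaluator(fn) if cache else fn


@dataclass
class SearchTrace:
    """Per-step (or per-generation) progress of a subset search."""

    entries: list[dict] = field(default_factory=list)

    def log(self, **kwargs) -> None:
        self.entries.append(kwargs)

    @property
    def best_fitnesses(self) -> list[float]:
        return [e["best_fitness"] for e in self.entries]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.entries)


def forward_wfss(
    X, y, evaluator: Evaluator, d: int | None = None
) -> tuple[FeatureSubset, SearchTrace]:
    """Greedy forward selection: repeatedly add the feature whose addition
    most (strictly) improves fitness; stop when none does.  Ties go to
    the lowest feature index; a constant evaluator yields the empty set."""
    d = d if d is not None else np.asarray(getattr(X, "values", X)).shape[1]
    if d < 1:
        raise SpecError("need at least one feature")
    mask = np.zeros(d, dtype=bool)
    # baseline = evaluator's own empty-mask value (0 for CV evaluators);
    # a constant evaluator therefore never strictly improves and the
    # search returns the empty set
    current = float(evaluator(mask))
    trace = SearchTrace()
    while True:
        best_j, best_f = None, current
        for j in range(d):
            if mask[j]:
                continue
            cand = mask.copy()
            cand[j] = True
            f = evaluator(cand)
            if f > best_f:
                best_f, best_j = f, j
        if best_j is None:
            break
        mask[best_j] = True
        current = best_f
        trace.log(step=len(trace.entries), action="add", index=best_j,
                  best_fitness=current, size=int(mask.sum()))
    return FeatureSubset(mask, "forward_wfss"), trace


def backward_wfss(
    X, y, evaluator: Evaluator, d: int | None = None
) -> tuple[FeatureSubset, SearchTrace]:
    """Greedy backward elimination: repeatedly drop the feature whose
    removal most improves (or least harms) fitness; stop once the best
    removal would strictly lower it.  Ties go to the lowest index."""
    d = d if d is not None else np.asarray(getattr(X, "values", X)).shape[1]
    if d < 1:
        raise SpecError("need at least one feature")
    mask = np.ones(d, dtype=bool)
    current = evaluator(mask)
    trace = SearchTrace()
    trace.log(step=0, action="start", index=-1, best_fitness=current, size=d)
    while mask.any():
        best_j, best_f = None, -np.inf
        for j in np.flatnonzero(mask):
            cand = mask.copy()
            cand[j] = False
            f = evaluator(cand) if cand.any() else 0.0
            if f > best_f:
                best_f, best_j = f, int(j)
        if best_j is None or best_f < current:
            break
        mask[best_j] = False
        current = best_f
        trace.log(step=len(trace.entries), action="remove", index=best_j,
                  best_fitness=current, size=int(mask.sum()))
    return FeatureSubset(mask, "backward_wfss"), trace


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings: population 1000, 100 generations,
    crossover 0.05, mutation 0.03 by default."""

    population_size: int = 1000
    generations: int = 100
    crossover_probability: float = 0.05
    mutation_probability: float = 0.03
    elitism_count: int = 1
    selection: str = "tournament"  # or "roulette"
    init_bit_probability: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise SpecError("population_size must be >= 2")
        if self.generations < 1:
            raise SpecError("generations must be >= 1")
        for name in ("crossover_probability", "mutation_probability",
                     "init_bit_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise SpecError("elitism_count out of range")
        if self.selection not in ("tournament", "roulette"):
            raise SpecError(f"unknown selection scheme {self.selection!r}")


def _pick_parent(fitness: np.ndarray, rng: np.random.Generator, scheme: str) -> int:
    if scheme == "tournament":
        i, j = rng.integers(fitness.size, size=2)
        if fitness[i] != fitness[j]:
            return int(i if fitness[i] > fitness[j] else j)
        return int(min(i, j))
    # roulette: probability proportional to fitness shifted to be positive
    w = fitness - fitness.min() + 1e-12
    return int(rng.choice(fitness.size, p=w / w.sum()))


def ga_select(
    X, y, evaluator: Evaluator, config: GAConfig, d: int | None = None
) -> tuple[FeatureSubset, SearchTrace]:
    """Evolutionary search over binary feature masks.

    Each generation: the ``elitism_count`` best individuals carry over
    unchanged, then children are bred by picking two parents by
    tournament (two contenders, the fitter wins), applying single-point
    crossover with ``crossover_probability`` per pair, and flipping each
    bit with ``mutation_probability``.  Returns the best individual ever
    evaluated; with elitism ≥ 1 the traced best fitness is
    non-decreasing.
    """
    config.validate()
    d = d if d is not None else np.asarray(getattr(X, "values", X)).shape[1]
    if d < 1:
        raise SpecError("need at least one feature")
    rng = np.random.default_rng(config.seed)
    P = config.population_size
    pop = rng.random((P, d)) < config.init_bit_probability

    def fit_of(mask: np.ndarray) -> float:
        return evaluator(mask) if mask.any() else 0.0

    fitness = np.array([fit_of(ind) for ind in pop])
    # empty-set baseline: the search never returns anything worse than it
    best_mask = np.zeros(d, dtype=bool)
    best_fit = 0.0
    gen0 = int(np.argmax(fitness))
    if fitness[gen0] > best_fit:
        best_fit, best_mask = float(fitness[gen0]), pop[gen0].copy()
    trace = SearchTrace()

    for gen in range(config.generations):
        order = np.lexsort((pop.sum(axis=1), -fitness))
        new = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(new) < P:
            a = _pick_parent(fitness, rng, config.selection)
            b = _pick_parent(fitness, rng, config.selection)
            c1, c2 = pop[a].copy(), pop[b].copy()
            if d > 1 and rng.random() < config.crossover_probability:
                point = int(rng.integers(1, d))
                c1[point:], c2[point:] = pop[b][point:].copy(), pop[a][point:].copy()
            for child in (c1, c2):
                flips = rng.random(d) < config.mutation_probability
                child ^= flips
                if len(new) < P:
                    new.append(child)
        pop = np.array(new)
        fitness = np.array([fit_of(ind) for ind in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit or (
            fitness[gen_best] == best_fit
            and pop[gen_best].sum() < best_mask.sum()
        ):
            best_fit = float(fitness[gen_best])
            best_mask = pop[gen_best].copy()
        trace.log(generation=gen, best_fitness=best_fit,
                  mean_fitness=float(fitness.mean()),
                  best_size=int(best_mask.sum()))
    return FeatureSubset(best_mask, "ga"), trace


def exhaustive_select(
    X, y, evaluator: Evaluator, d: int | None = None, max_features: int = 16
) -> FeatureSubset:
    """Evaluate every one of the 2^d masks and return the argmax.

    Ties prefer the smaller subset, then the lexicographically smallest
    index tuple.  Refuses d > max_features (the cost is exponential; this
    exists as a ground-truth oracle for the heuristic searches).
    """
    d = d if d is not None else np.asarray(getattr(X, "values", X)).shape[1]
    if d > max_features:
        raise SpecError(f"exhaustive search refused for d={d} > {max_features}")
    best_key = None
    best_mask = np.zeros(d, dtype=bool)
    for bits in range(2**d):
        mask = np.array([(bits >> j) & 1 for j in range(d)], dtype=bool)
        f = evaluator(mask) if mask.any() else 0.0
        key = (-f, int(mask.sum()), tuple(np.flatnonzero(mask)))
        if best_key is None or key < best_key:
            best_key, best_mask = key, mask
    return FeatureSubset(best_mask, "exhaustive")
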