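"""Feature-subset search strategies.

The feature space (101 composition features at full scale) is searched with
three families of methods, all scored by the cross-validated fitness
criterion from :mod:`hostsieve.evaluation`:

* a bottom-up wrapper search: exhaustively evaluate every subset of size
  1..3, then repeatedly pick one of the 100 best subsets at random and grow
  it by one feature, until the top-100 membership is stable for 1000
  consecutive rounds;
* a genetic algorithm over binary inclusion vectors with tournament
  selection, two-point crossover and per-bit mutation;
* embedded/filter selectors: the Lasso path of an L1 logistic regression,
  recursive feature elimination driven by linear-SVC weights, and ANOVA-F
  ranking (select-k-best).

Every subset evaluation is memoised, keyed by the canonical subset plus the
hyperparameters, because the searches revisit subsets by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .evaluation import CVResult, cross_validate
from .features import StandardizationParams
from .models import C_GRID, Hyperparameters

__all__ = [
    "SubsetEvaluator",
    "SelectionResult",
    "bottom_up_search",
    "ga_search",
    "embedded_select",
    "write_selection_log",
]

Subset = tuple[int, ...]


def canonical(subset: Sequence[int]) -> Subset:
    """Sorted, duplicate-free tuple of feature indices."""
    return tuple(sorted(set(int(i) for i in subset)))


def subset_to_bitmask(subset: Sequence[int], n_features: int) -> str:
    bits = ["0"] * n_features
    for i in subset:
        bits[i] = "1"
    return "".join(bits)


@dataclass
class SelectionResult:
    """Outcome of one subset search: the winner plus the full evaluation log."""

    best_subset: Subset
    best_cv: CVResult
    log: dict[Subset, float]
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def best_fitness(self) -> float:
        return self.best_cv.fitness


class SubsetEvaluator:
    """Memoised fitness evaluation of feature subsets.

    The cross-validation fold assignment is fixed once (from ``folds`` or
    drawn from ``seed``) so every subset is scored on identical splits and
    fitness values are comparable across the search.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        hp: Hyperparameters,
        seed: int = 0,
        folds: np.ndarray | None = None,
        n_folds: int = 5,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.hp = hp
        self.seed = seed
        self.n_folds = n_folds
        self.folds = folds
        self._cache: dict[Subset, CVResult] = {}

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_evaluations(self) -> int:
        return len(self._cache)

    def is_cached(self, subset: Sequence[int]) -> bool:
        return canonical(subset) in self._cache

    def cv_result(self, subset: Sequence[int]) -> CVResult:
        key = canonical(subset)
        if not key:
            raise ValueError("cannot evaluate an empty feature subset")
        if key not in self._cache:
            self._cache[key] = cross_validate(
                self.X,
                self.y,
                self.hp.with_subset(key),
                folds=self.folds,
                seed=self.seed,
                n_folds=self.n_folds,
            )
        return self._cache[key]

    def fitness(self, subset: Sequence[int]) -> float:
        return self.cv_result(subset).fitness

    def log(self) -> dict[Subset, float]:
        return {k: v.fitness for k, v in self._cache.items()}

    def best(self) -> tuple[Subset, CVResult]:
        key = max(
            self._cache, key=lambda s: (self._cache[s].fitness, [-i for i in s])
        )
        return key, self._cache[key]


def _ranked(evaluator: SubsetEvaluator) -> list[Subset]:
    """Evaluated subsets sorted by fitness (desc), canonical order on ties."""
    return sorted(evaluator.log(), key=lambda s: (-evaluator.fitness(s), s))


def bottom_up_search(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    top_k: int = 100,
    patience: int = 1000,
    init_max_len: int = 3,
    seed: int = 0,
    folds: np.ndarray | None = None,
    n_folds: int = 5,
    max_rounds: int | None = None,
) -> SelectionResult:
    """Bottom-up wrapper feature selection.

    1. Exhaustively evaluate every subset of size 1..``init_max_len``.
    2. Sort all evaluated subsets by fitness.
    3. Pick one of the ``top_k`` best uniformly at random (the randomness
       prevents premature convergence to a local fitness maximum), generate
       all supersets one feature larger, and evaluate each of them plus any
       of their same-size-as-parent subsets not seen before.
    4. Repeat from 2 until the ``top_k`` membership is unchanged for
       ``patience`` consecutive rounds (``patience=0`` stops after the
       initial enumeration).

    Returns the best subset ever evaluated.  ``max_rounds`` is a hard cap
    for desk-scale runs; None means unlimited.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if patience < 0:
        raise ValueError("patience must be >= 0")
    rng = np.random.default_rng(seed)
    evaluator = SubsetEvaluator(X, y, hp, seed=seed, folds=folds, n_folds=n_folds)
    n = evaluator.n_features

    for size in range(1, min(init_max_len, n) + 1):
        for combo in itertools.combinations(range(n), size):
            evaluator.cv_result(combo)

    stable_rounds = 0
    rounds = 0
    prev_top = set(_ranked(evaluator)[:top_k])
    while patience > 0 and stable_rounds < patience:
        if max_rounds is not None and rounds >= max_rounds:
            break
        top = _ranked(evaluator)[:top_k]
        basis = top[int(rng.integers(len(top)))]
        for feat in range(n):
            if feat in basis:
                continue
            child = canonical(basis + (feat,))
            evaluator.cv_result(child)
            # evaluate any unseen same-length-as-basis subsets of the child
            for sub in itertools.combinations(child, len(basis)):
                if not evaluator.is_cached(sub):
                    evaluator.cv_result(sub)
        rounds += 1
        new_top = set(_ranked(evaluator)[:top_k])
        if new_top == prev_top:
            stable_rounds += 1
        else:
            stable_rounds = 0
        prev_top = new_top

    best_subset, best_cv = evaluator.best()
    return SelectionResult(
        best_subset=best_subset,
        best_cv=best_cv,
        log=evaluator.log(),
        seed=seed,
        settings={
            "method": "bottom_up",
            "top_k": top_k,
            "patience": patience,
            "init_max_len": init_max_len,
            "rounds": rounds,
        },
    )


def _ensure_nonempty(individual: np.ndarray, rng: np.random.Generator) -> None:
    if not individual.any():
        individual[int(rng.integers(len(individual)))] = True


def _two_point_crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> None:
    n = len(a)
    if n < 2:
        return
    i, j = sorted(rng.choice(n, size=2, replace=False))
    a[i : j + 1], b[i : j + 1] = b[i : j + 1].copy(), a[i : j + 1].copy()


def ga_search(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    pop_size: int = 100,
    generations: int = 200,
    tournament_size: int = 3,
    crossover_p: float = 0.5,
    mutation_p: float | None = None,
    repeats: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
    n_folds: int = 5,
) -> SelectionResult:
    """Genetic-algorithm subset search over binary inclusion vectors.

    Individuals are fixed-length bit vectors (one bit per feature).  Each
    generation applies tournament selection, two-point crossover with
    probability ``crossover_p`` and independent per-bit mutation (default
    rate 1/n_features).  A run terminates after ``generations`` generations
    or as soon as the whole population is identical; the search is repeated
    ``repeats`` times and the best individual over all runs wins.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    evaluator = SubsetEvaluator(X, y, hp, seed=seed, folds=folds, n_folds=n_folds)
    n = evaluator.n_features
    if mutation_p is None:
        mutation_p = 1.0 / n

    master = np.random.default_rng(seed)
    generations_run = []
    for rep in range(repeats):
        rng = np.random.default_rng(master.integers(2**31))
        pop = rng.random((pop_size, n)) < 0.5
        for ind in pop:
            _ensure_nonempty(ind, rng)
        fits = np.array([evaluator.fitness(np.flatnonzero(ind)) for ind in pop])

        gen = 0
        while gen < generations:
            if (pop == pop[0]).all():
                break  # population converged to a single individual
            # tournament selection
            new_pop = np.empty_like(pop)
            for i in range(pop_size):
                contenders = rng.integers(pop_size, size=tournament_size)
                new_pop[i] = pop[contenders[np.argmax(fits[contenders])]]
            # crossover on consecutive pairs
            for i in range(0, pop_size - 1, 2):
                if rng.random() < crossover_p:
                    _two_point_crossover(new_pop[i], new_pop[i + 1], rng)
            # per-bit mutation
            flip = rng.random(new_pop.shape) < mutation_p
            new_pop ^= flip
            for ind in new_pop:
                _ensure_nonempty(ind, rng)
            pop = new_pop
            fits = np.array([evaluator.fitness(np.flatnonzero(ind)) for ind in pop])
            gen += 1
        generations_run.append(gen)

    best_subset, best_cv = evaluator.best()
    return SelectionResult(
        best_subset=best_subset,
        best_cv=best_cv,
        log=evaluator.log(),
        seed=seed,
        settings={
            "method": "ga",
            "pop_size": pop_size,
            "generations": generations,
            "generations_run": generations_run,
            "tournament_size": tournament_size,
            "crossover_p": crossover_p,
            "mutation_p": mutation_p,
            "repeats": repeats,
        },
    )


def embedded_select(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    hp: Hyperparameters | None = None,
    C_grid: Sequence[float] = C_GRID,
    k_grid: Sequence[int] | None = None,
    seed: int = 0,
    folds: np.ndarray | None = None,
    n_folds: int = 5,
) -> SelectionResult:
    """Embedded / filter feature selection: ``lasso``, ``rfe`` or ``kbest``.

    * ``lasso`` - L1-penalised logistic regression fitted at every C on the
      powers-of-two grid; the candidate subset at each C is the set of
      features with nonzero coefficients, and the C whose subset maximises
      the cross-validated fitness (of an LR at that C) wins.
    * ``rfe`` - recursive feature elimination ranked by linear-SVC weight
      magnitudes (one feature dropped per step); candidate subset sizes from
      ``k_grid`` are scored by fitness with the SVC.
    * ``kbest`` - features ranked by the ANOVA F statistic between feature
      and label (constant features get F = 0); ``k`` chosen by fitness with
      the SVC.
    """
    method = method.lower()
    if method in ("scad", "quipt"):
        raise NotImplementedError(
            f"{method!r} is provided by external packages and is not part of "
            "hostsieve; supported methods: lasso, rfe, kbest"
        )
    if method not in ("lasso", "rfe", "kbest"):
        raise ValueError("method must be one of: lasso, rfe, kbest")

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[1]
    if k_grid is None:
        k_grid = range(1, n + 1)
    Z = StandardizationParams.fit(X).transform(X)

    candidates: list[tuple[Subset, Hyperparameters]] = []
    if method == "lasso":
        for C in C_grid:
            lr = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=seed
            )
            lr.fit(Z, y)
            subset = canonical(np.flatnonzero(np.abs(lr.coef_[0]) > 0))
            if subset:
                candidates.append((subset, Hyperparameters("lr", C=C)))
        if not candidates:
            raise RuntimeError("lasso path selected no features at any C")
    else:
        base_hp = hp if hp is not None else Hyperparameters("svc")
        if method == "kbest":
            with np.errstate(divide="ignore", invalid="ignore"):
                F, _ = f_classif(Z, y)
            F = np.nan_to_num(F, nan=0.0)
            order = np.argsort(-F, kind="stable")
        else:  # rfe: drop the smallest |weight| one at a time
            remaining = list(range(n))
            elimination: list[int] = []
            while len(remaining) > 1:
                svc = SVC(kernel="linear", C=base_hp.C, random_state=seed)
                svc.fit(Z[:, remaining], y)
                w = np.abs(svc.coef_[0])
                drop = remaining[int(np.argmin(w))]
                elimination.append(drop)
                remaining.remove(drop)
            order = np.array(remaining + elimination[::-1])
        for k in k_grid:
            if 1 <= k <= n:
                candidates.append(
                    (canonical(order[:k]), base_hp)
                )

    # score every candidate subset with the shared fold assignment
    log: dict[Subset, float] = {}
    best: tuple[float, Subset, CVResult, Hyperparameters] | None = None
    evaluators: dict[Hyperparameters, SubsetEvaluator] = {}
    for subset, cand_hp in candidates:
        ev = evaluators.setdefault(
            cand_hp, SubsetEvaluator(X, y, cand_hp, seed=seed, folds=folds, n_folds=n_folds)
        )
        cv = ev.cv_result(subset)
        log[subset] = cv.fitness
        if best is None or cv.fitness > best[0]:
            best = (cv.fitness, subset, cv, cand_hp)

    assert best is not None
    return SelectionResult(
        best_subset=best[1],
        best_cv=best[2],
        log=log,
        seed=seed,
        settings={"method": method, "hyperparameters": best[3]},
    )


def write_selection_log(
    path: str | Path, result: SelectionResult, n_features: int
) -> None:
    """TSV dump of the search log: bitmask, fitness, per-subset CV metrics."""
    rows = sorted(result.log.items(), key=lambda kv: -kv[1])
    with open(path, "w") as fh:
        fh.write("subset_bitmask\tn_features\tfitness\n")
        for subset, fit in rows:
            fh.write(
                f"{subset_to_bitmask(subset, n_features)}\t{len(subset)}\t{fit:.10g}\n"
            )
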