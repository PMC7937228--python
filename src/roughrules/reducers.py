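"""Heuristic reduct search: Johnson greedy cover and a genetic algorithm.

The Johnson reducer repeatedly picks the feature with the largest total
weight of uncovered clauses and removes everything it covers — a
deterministic, linear-time route to a single reduct.  The genetic
reducer searches bitstring-encoded feature subsets with a fitness that
trades off subset cost against the fraction of clauses hit, keeping
every subset whose hitting fraction reaches the approximation degree
epsilon; it can recover many (on small instances, all) minimal reducts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .discern import DiscernibilityFamily, is_hitting_set
from .tables import ConfigError

__all__ = [
    "Reduct",
    "JohnsonParams",
    "GeneticParams",
    "johnson_reduct",
    "genetic_reducts",
    "minimize_hitting_set",
    "fitness",
]


@dataclass(frozen=True)
class Reduct:
    features: frozenset
    method: str  # johnson | genetic | exhaustive
    score: float = 0.0

    def sorted_features(self, universe: tuple[str, ...]) -> tuple[str, ...]:
        order = {f: i for i, f in enumerate(universe)}
        return tuple(sorted(self.features, key=order.__getitem__))


@dataclass(frozen=True)
class JohnsonParams:
    """``weights`` maps a clause (frozenset) to a positive weight;
    unweighted clauses count 1 per multiset occurrence."""

    weights: dict = field(default_factory=dict)
    minimize: bool = True

    def weight(self, clause: frozenset) -> float:
        w = self.weights.get(clause, 1.0)
        if w <= 0:
            raise ConfigError("clause weights must be strictly positive")
        return w


@dataclass(frozen=True)
class GeneticParams:
    alpha: float = 0.9
    epsilon: float = 1.0
    cost: Callable[[frozenset], float] | None = None  # default |B|
    population_size: int = 70
    generations: int = 200
    crossover_prob: float = 0.6
    mutation_prob: float | None = None  # default 1/|A|
    elite_count: int = 2
    keep_list_size: int = 256
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError("alpha must lie in [0, 1]")
        if not (0.0 < self.epsilon <= 1.0):
            raise ConfigError("epsilon must lie in (0, 1]")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        for name in ("crossover_prob",):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")


def minimize_hitting_set(fam: DiscernibilityFamily, features: frozenset) -> frozenset:
    """Drop redundant features in reverse feature order until minimal."""
    order = {f: i for i, f in enumerate(fam.universe_features)}
    current = set(features)
    for f in sorted(features, key=order.__getitem__, reverse=True):
        trial = current - {f}
        if trial and is_hitting_set(fam, trial):
            current = trial
    return frozenset(current)


def johnson_reduct(
    fam: DiscernibilityFamily, params: JohnsonParams | None = None
) -> Reduct:
    """Greedy weighted cover of the discernibility clauses.

    Loop: pick the feature maximizing the summed weight of uncovered
    clauses containing it (ties broken by feature order), add it, drop
    the clauses it covers, until none remain.  The result is optionally
    post-processed to subset-minimality (default on).
    """
    if params is None:
        params = JohnsonParams()
    if not fam.clauses:
        raise ConfigError("empty discernibility family: nothing to cover")
    remaining = list(fam.clauses)
    chosen: list[str] = []
    total = 0.0
    while remaining:
        best_f, best_w = None, -1.0
        for f in fam.universe_features:
            if f in chosen:
                continue
            w = sum(params.weight(c) for c in remaining if f in c)
            if w > best_w:
                best_f, best_w = f, w
        assert best_f is not None
        chosen.append(best_f)
        total += best_w
        remaining = [c for c in remaining if best_f not in c]
    features = frozenset(chosen)
    if params.minimize:
        features = minimize_hitting_set(fam, features)
    return Reduct(features=features, method="johnson", score=total)


def fitness(
    fam: DiscernibilityFamily, subset: frozenset, params: GeneticParams
) -> float:
    """Cost/hitting-fraction trade-off rewarding hitting sets.

    f(B) = (1-alpha) * (cost(A)-cost(B))/cost(A)
         + alpha * min(epsilon, |{S : S n B != 0}| / |S|)
    """
    cost = params.cost or (lambda b: float(len(b)))
    cost_a = cost(frozenset(fam.universe_features))
    if cost_a <= 0:
        raise ConfigError("cost of the full feature set must be positive")
    hit = sum(1 for c in fam.clauses if c & subset)
    frac = hit / len(fam.clauses) if fam.clauses else 1.0
    return (1.0 - params.alpha) * (cost_a - cost(subset)) / cost_a + params.alpha * min(
        params.epsilon, frac
    )


def _clause_matrix(fam: DiscernibilityFamily) -> np.ndarray:
    feat_pos = {f: i for i, f in enumerate(fam.universe_features)}
    mat = np.zeros((len(fam.clauses), len(fam.universe_features)), dtype=bool)
    for i, c in enumerate(fam.clauses):
        for f in c:
            mat[i, feat_pos[f]] = True
    return mat


def genetic_reducts(
    fam: DiscernibilityFamily, params: GeneticParams | None = None
) -> list[Reduct]:
    """GA search over feature subsets; returns minimized keep-list.

    Every individual whose hitting fraction reaches epsilon enters a
    keep-list of distinct subsets; at the end each kept subset is
    reduced to a subset-minimal hitting set, deduplicated and ordered
    deterministically (size, then feature order).  Reproducible for a
    fixed seed.
    """
    if params is None:
        params = GeneticParams()
    if not fam.clauses:
        raise ConfigError("empty discernibility family: nothing to hit")
    rng = np.random.default_rng(params.seed)
    n_feat = len(fam.universe_features)
    n_clauses = len(fam.clauses)
    clause_mat = _clause_matrix(fam)  # clauses x features
    cost_fn = params.cost or (lambda b: float(len(b)))
    cost_a = cost_fn(frozenset(fam.universe_features))
    mut_p = params.mutation_prob if params.mutation_prob is not None else 1.0 / n_feat
    default_cost = params.cost is None

    pop = rng.random((params.population_size, n_feat)) < 0.5
    keep: dict[frozenset, None] = {}

    def evaluate(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hit = (p.astype(np.int64) @ clause_mat.T.astype(np.int64)) > 0
        frac = hit.sum(axis=1) / n_clauses
        if default_cost:
            costs = p.sum(axis=1).astype(float)
        else:
            costs = np.array(
                [
                    cost_fn(frozenset(np.array(fam.universe_features)[row]))
                    for row in p
                ]
            )
        fit = (1.0 - params.alpha) * (cost_a - costs) / cost_a + params.alpha * np.minimum(
            params.epsilon, frac
        )
        return fit, frac

    feats_arr = np.array(fam.universe_features, dtype=object)
    for _ in range(params.generations):
        fit, frac = evaluate(pop)
        for i in np.flatnonzero(frac >= params.epsilon):
            fs = frozenset(feats_arr[pop[i]])
            if fs and fs not in keep and len(keep) < params.keep_list_size:
                keep[fs] = None
        # tournament selection (size 2) + elitism
        elite_idx = np.argsort(fit)[::-1][: params.elite_count]
        a = rng.integers(0, params.population_size, params.population_size)
        b = rng.integers(0, params.population_size, params.population_size)
        winners = np.where(fit[a] >= fit[b], a, b)
        children = pop[winners].copy()
        # one-point crossover on consecutive pairs
        for i in range(0, params.population_size - 1, 2):
            if rng.random() < params.crossover_prob and n_feat > 1:
                point = int(rng.integers(1, n_feat))
                tmp = children[i, point:].copy()
                children[i, point:] = children[i + 1, point:]
                children[i + 1, point:] = tmp
        children ^= rng.random(children.shape) < mut_p
        children[: params.elite_count] = pop[elite_idx]
        pop = children
    fit, frac = evaluate(pop)
    for i in np.flatnonzero(frac >= params.epsilon):
        fs = frozenset(feats_arr[pop[i]])
        if fs and fs not in keep and len(keep) < params.keep_list_size:
            keep[fs] = None

    if not keep:
        warnings.warn(
            "genetic reducer found no subset reaching the requested hitting "
            "fraction; returning best-effort empty list",
            stacklevel=2,
        )
        return []
    minimized: dict[frozenset, None] = {}
    for fs in keep:
        if params.epsilon >= 1.0:
            fs = minimize_hitting_set(fam, fs)
        minimized.setdefault(fs, None)
    order = {f: i for i, f in enumerate(fam.universe_features)}
    result = sorted(
        minimized, key=lambda r: (len(r), sorted(r, key=order.__getitem__))
    )
    return [
        Reduct(
            features=r,
            method="genetic",
            score=fitness(fam, r, params),
        )
        for r in result
    ]
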