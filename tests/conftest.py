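"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from roughrules.discern import DiscernibilityFamily
from roughrules.synthgen import fixture_tables
from roughrules.tables import DecisionTable


@pytest.fixture(scope="session")
def table1() -> DecisionTable:
    return fixture_tables()["table1"]


@pytest.fixture(scope="session")
def table2() -> DecisionTable:
    return fixture_tables()["table2"]


# ---------------------------------------------------------------------------
# oracles: deliberately naive, independent of the library implementations
# ---------------------------------------------------------------------------

def brute_force_minimal_hitting_sets(fam: DiscernibilityFamily) -> list[frozenset]:
    """2^|A| scan: every subset, hitting check, subset-minimality check."""
    universe = list(fam.universe_features)
    hitting = []
    for r in range(len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            s = frozenset(combo)
            if all(c & s for c in fam.clauses):
                hitting.append(s)
    minimal = [
        h for h in hitting if not any(o < h for o in hitting)
    ]
    order = {f: i for i, f in enumerate(universe)}
    return sorted(minimal, key=lambda s: (len(s), sorted(s, key=order.__getitem__)))


def hypergeom_upper_tail_by_enumeration(n: int, n_d: int, y: int, x: int) -> float:
    """P(X >= x) by counting all C(n, y) draws of y objects from a
    universe where the first n_d objects carry the decision."""
    marked = set(range(n_d))
    total = 0
    ge = 0
    for combo in itertools.combinations(range(n), y):
        total += 1
        if len(marked.intersection(combo)) >= x:
            ge += 1
    return ge / total if total else 1.0


def random_discrete_table(
    rng: np.random.Generator,
    n_objects: int,
    n_features: int,
    n_levels: int = 2,
    n_classes: int = 2,
) -> DecisionTable:
    values = tuple(
        tuple(str(rng.integers(0, n_levels)) for _ in range(n_features))
        for _ in range(n_objects)
    )
    decisions = tuple(f"c{rng.integers(0, n_classes)}" for _ in range(n_objects))
    return DecisionTable(
        object_ids=tuple(f"o{i}" for i in range(n_objects)),
        feature_names=tuple(f"a{j}" for j in range(n_features)),
        values=values,
        decision_name="cls",
        decisions=decisions,
        value_kind=tuple("discrete" for _ in range(n_features)),
    )
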