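"""Indiscernibility, rough approximations and discernibility reducts.

Two objects are indiscernible under a feature subset B when they agree
on every feature of B; the induced equivalence classes partition the
universe.  Pairs of equivalence classes with different (generalized)
decisions must be told apart, and the features able to do so form one
clause of the discernibility family.  Minimal hitting sets of that
family are the reducts: minimal feature subsets preserving the
discernibility of the full feature set.  This module also provides the
exhaustive (brute-force-validated) reduct enumeration used as the
ground-truth oracle for the heuristic reducers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .tables import ConfigError, DecisionTable, DISCRETE

__all__ = [
    "Partition",
    "ApproximationRegions",
    "DiscernibilityFamily",
    "indiscernibility_partition",
    "approximate",
    "generalized_table",
    "discernibility_family",
    "enumerate_minimal_hitting_sets",
    "is_hitting_set",
]

#: decision labels of a generalized row are joined with this separator
GENERALIZED_SEP = "|"

EXHAUSTIVE_FEATURE_LIMIT = 20


@dataclass(frozen=True)
class Partition:
    """Equivalence classes of agreement on ``generating_features``."""

    blocks: tuple[frozenset, ...]
    generating_features: frozenset

    def block_of(self, object_id: str) -> frozenset:
        for b in self.blocks:
            if object_id in b:
                return b
        raise KeyError(object_id)


@dataclass(frozen=True)
class ApproximationRegions:
    lower: frozenset
    upper: frozenset
    boundary: frozenset
    outside: frozenset
    target: frozenset
    features: frozenset


@dataclass(frozen=True)
class DiscernibilityFamily:
    """Multiset of feature subsets, one per decision-discernible pair.

    ``clauses`` keeps duplicates (they carry weight in the Johnson
    reducer); ``universe_features`` records the full feature order A.
    """

    clauses: tuple[frozenset, ...]
    universe_features: tuple[str, ...]

    def __post_init__(self) -> None:
        for c in self.clauses:
            if not c:
                raise ValueError("empty discernibility clause")

    def counts(self) -> Counter:
        return Counter(self.clauses)

    def absorbed(self) -> tuple[frozenset, ...]:
        """Unique clauses with supersets of other clauses removed."""
        unique = sorted(set(self.clauses), key=lambda c: (len(c), sorted(c)))
        kept: list[frozenset] = []
        for c in unique:
            if not any(k <= c for k in kept):
                kept.append(c)
        return tuple(kept)

    def to_lines(self) -> str:
        return "\n".join(",".join(sorted(c)) for c in self.clauses)


def _block_key(dt: DecisionTable, row_index: int, feature_idx: list[int]) -> tuple:
    row = dt.values[row_index]
    return tuple(row[j] for j in feature_idx)


def indiscernibility_partition(dt: DecisionTable, features) -> Partition:
    """Partition of the universe by agreement on every feature in B.

    The empty subset yields a single block (all objects agree on
    nothing).  Blocks are ordered by their smallest contained object
    index for determinism.
    """
    dt.require_discrete()
    feats = list(features)
    idx = [dt.feature_index(f) for f in feats]
    groups: dict[tuple, list[str]] = {}
    order: dict[tuple, int] = {}
    for i, oid in enumerate(dt.object_ids):
        key = _block_key(dt, i, idx)
        groups.setdefault(key, []).append(oid)
        order.setdefault(key, i)
    blocks = tuple(
        frozenset(groups[k]) for k in sorted(groups, key=lambda k: order[k])
    )
    return Partition(blocks=blocks, generating_features=frozenset(feats))


def approximate(dt: DecisionTable, features, target) -> ApproximationRegions:
    """Lower/upper approximations of the object set X under IND(B)."""
    universe = set(dt.object_ids)
    x = frozenset(target)
    if not x <= universe:
        raise ConfigError(f"target objects not in universe: {sorted(x - universe)}")
    part = indiscernibility_partition(dt, features)
    lower: set = set()
    upper: set = set()
    for b in part.blocks:
        if b <= x:
            lower |= b
        if b & x:
            upper |= b
    lower_f, upper_f = frozenset(lower), frozenset(upper)
    return ApproximationRegions(
        lower=lower_f,
        upper=upper_f,
        boundary=upper_f - lower_f,
        outside=frozenset(universe) - upper_f,
        target=x,
        features=frozenset(features),
    )


def generalized_decisions(dt: DecisionTable) -> list[tuple[frozenset, frozenset]]:
    """Per equivalence class of IND(A): (block, set of decision labels).

    Labels already containing the separator are split, so an input that
    is itself a generalized table round-trips.
    """
    part = indiscernibility_partition(dt, dt.feature_names)
    by_id = dict(zip(dt.object_ids, dt.decisions))
    out = []
    for b in part.blocks:
        labels: set[str] = set()
        for oid in b:
            labels.update(by_id[oid].split(GENERALIZED_SEP))
        out.append((b, frozenset(labels)))
    return out


def generalized_table(dt: DecisionTable) -> DecisionTable:
    """Collapse indiscernible objects into one row per equivalence class.

    The decision becomes the sorted, ``|``-joined set of labels seen in
    the class; the class cardinality is retained in ``row_weights``.
    """
    dt.require_discrete()
    pos = {oid: i for i, oid in enumerate(dt.object_ids)}
    rows, ids, decs, weights = [], [], [], []
    for b, labels in generalized_decisions(dt):
        rep = min(b, key=lambda o: pos[o])
        rows.append(dt.values[pos[rep]])
        ids.append(rep)
        decs.append(GENERALIZED_SEP.join(sorted(labels)))
        weights.append(sum(dt.row_weights[pos[o]] for o in b))
    return DecisionTable(
        object_ids=tuple(ids),
        feature_names=dt.feature_names,
        values=tuple(rows),
        decision_name=dt.decision_name,
        decisions=tuple(decs),
        value_kind=tuple(DISCRETE for _ in dt.feature_names),
        row_weights=tuple(weights),
    )


def discernibility_family(dt: DecisionTable) -> DiscernibilityFamily:
    """Decision-relative discernibility clauses over equivalence classes.

    For every unordered pair of IND(A)-classes whose generalized
    decision sets are unequal, emit the set of features on which the
    classes differ.  Clause order is deterministic (pairs in block
    order), duplicates are retained.
    """
    dt.require_discrete()
    gen = generalized_decisions(dt)
    if len({lbl for _, labels in gen for lbl in labels}) < 2:
        return DiscernibilityFamily(clauses=(), universe_features=dt.feature_names)
    pos = {oid: i for i, oid in enumerate(dt.object_ids)}
    reps = [min(b, key=lambda o: pos[o]) for b, _ in gen]
    rows = [dt.values[pos[r]] for r in reps]
    clauses: list[frozenset] = []
    n = len(gen)
    for i in range(n):
        for j in range(i + 1, n):
            if gen[i][1] == gen[j][1]:
                continue
            diff = frozenset(
                f
                for f, a, b in zip(dt.feature_names, rows[i], rows[j])
                if a != b
            )
            assert diff, "decision-distinct classes must differ on some feature"
            clauses.append(diff)
    return DiscernibilityFamily(clauses=tuple(clauses), universe_features=dt.feature_names)


def is_hitting_set(fam: DiscernibilityFamily, features) -> bool:
    fs = frozenset(features)
    return all(c & fs for c in fam.clauses)


def _minimal_hitting_sets(clauses: tuple[frozenset, ...], universe: tuple[str, ...]):
    """Branch-and-bound enumeration over absorbed clauses."""
    order = {f: i for i, f in enumerate(universe)}
    results: set[frozenset] = set()

    def recurse(remaining: tuple[frozenset, ...], chosen: frozenset) -> None:
        if not remaining:
            if not any(r < chosen for r in results):
                results.difference_update({r for r in results if chosen < r})
                results.add(chosen)
            return
        # pruning: a superset of an already-found hitting set can never
        # be subset-minimal
        if any(r <= chosen for r in results):
            return
        clause = min(remaining, key=len)
        for f in sorted(clause, key=order.__getitem__):
            nxt = tuple(c for c in remaining if f not in c)
            recurse(nxt, chosen | {f})

    recurse(clauses, frozenset())
    # the branching can emit non-minimal sets; filter once more
    minimal = [
        r for r in results if not any(o < r for o in results)
    ]
    return sorted(minimal, key=lambda r: (len(r), sorted(r, key=order.__getitem__)))


def enumerate_minimal_hitting_sets(
    fam: DiscernibilityFamily, feature_limit: int = EXHAUSTIVE_FEATURE_LIMIT
) -> list[frozenset]:
    """All subset-minimal hitting sets of the clause family.

    Equivalently the prime implicants of the conjunctive discernibility
    function.  Refuses families over more than ``feature_limit``
    features (the problem is NP-hard); use the heuristic reducers then.
    Result sorted by size, then by feature order.
    """
    if len(fam.universe_features) > feature_limit:
        raise ConfigError(
            f"{len(fam.universe_features)} features exceeds the exhaustive "
            f"limit ({feature_limit}); use the johnson or genetic reducer"
        )
    if not fam.clauses:
        return []
    return _minimal_hitting_sets(fam.absorbed(), fam.universe_features)
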