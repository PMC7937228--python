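"""Co-prediction network export and per-rule visualization payloads.

Nodes are (feature = level) conjuncts, edges connect conjuncts that
co-occur in at least one retained rule of a class.  Each retained rule
contributes ``support_rhs * accuracy`` to every conjunct pair it
contains; node strength sums the incident edge strengths (isolated
nodes from single-conjunct rules keep their rules' own contributions).
The export targets generic graph tooling: an edge-list TSV plus the
rule-table interchange format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .rules import Rule, RuleModel, RuleStats
from .tables import ConfigError, DecisionTable

__all__ = [
    "RuleNetwork",
    "build_network",
    "write_edge_list",
    "rule_support_payload",
]


@dataclass(frozen=True)
class RuleNetwork:
    class_label: str
    nodes: tuple[tuple[str, str, float], ...]  # (feature, level, strength)
    edges: tuple[tuple[tuple[str, str], tuple[str, str], float, tuple[int, ...]], ...]


def build_network(
    model: RuleModel,
    class_label: str,
    max_p_adjusted: float = 0.05,
    min_support_rhs: int = 0,
) -> RuleNetwork:
    """Significance-filtered co-occurrence network for one class.

    Rules of ``class_label`` with adjusted P <= ``max_p_adjusted`` and
    RHS support >= ``min_support_rhs`` are retained; connection strength
    of a conjunct pair is the sum of ``support_rhs * accuracy`` over the
    retained rules containing both conjuncts.
    """
    retained: list[tuple[int, Rule, RuleStats]] = []
    for i, (rule, stats) in enumerate(model.rules):
        if rule.decision != class_label:
            continue
        if stats.p_adjusted > max_p_adjusted or stats.support_rhs < min_support_rhs:
            continue
        retained.append((i, rule, stats))
    if not retained:
        warnings.warn(
            f"no rules of class {class_label!r} pass the filter", stacklevel=2
        )
        return RuleNetwork(class_label=class_label, nodes=(), edges=())

    edge_strength: dict[tuple, float] = {}
    edge_rules: dict[tuple, list[int]] = {}
    node_strength: dict[tuple[str, str], float] = {}
    isolated_contrib: dict[tuple[str, str], float] = {}
    for i, rule, stats in retained:
        contribution = stats.support_rhs * stats.accuracy
        conjuncts = sorted(rule.conditions)
        for c in conjuncts:
            node_strength.setdefault(c, 0.0)
        if len(conjuncts) == 1:
            isolated_contrib[conjuncts[0]] = (
                isolated_contrib.get(conjuncts[0], 0.0) + contribution
            )
            continue
        for a_idx in range(len(conjuncts)):
            for b_idx in range(a_idx + 1, len(conjuncts)):
                key = (conjuncts[a_idx], conjuncts[b_idx])
                edge_strength[key] = edge_strength.get(key, 0.0) + contribution
                edge_rules.setdefault(key, []).append(i)
    for (a, b), w in edge_strength.items():
        node_strength[a] += w
        node_strength[b] += w
    # nodes touched only by single-conjunct rules keep those contributions
    for c, w in isolated_contrib.items():
        if node_strength[c] == 0.0:
            node_strength[c] = w

    nodes = tuple(
        (f, v, s)
        for (f, v), s in sorted(
            node_strength.items(), key=lambda kv: (-kv[1], kv[0])
        )
    )
    edges = tuple(
        (a, b, w, tuple(edge_rules[(a, b)]))
        for (a, b), w in sorted(
            edge_strength.items(), key=lambda kv: (-kv[1], kv[0])
        )
    )
    return RuleNetwork(class_label=class_label, nodes=nodes, edges=edges)


def write_edge_list(networks: list[RuleNetwork], path, delimiter: str = "\t") -> None:
    """Edge-list export: source, target, weight, class (one row per edge)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(("source", "target", "weight", "class")) + "\n")
        for net in networks:
            for (fa, va), (fb, vb), w, _rules in net.edges:
                fh.write(
                    delimiter.join(
                        (f"{fa}={va}", f"{fb}={vb}", f"{w:.6g}", net.class_label)
                    )
                    + "\n"
                )


def rule_support_payload(
    rule: Rule, stats: RuleStats, dt: DecisionTable
) -> dict[str, dict[str, list]]:
    """Per-conjunct data behind supporter-vs-rest boxplots.

    Splits the objects of a continuous companion table (aligned by id
    with the training data) into three groups: the rule's RHS support
    set, same-class objects outside the support set, and objects of the
    other classes; returns each group's values for every conjunct
    feature.
    """
    missing = set(stats.support_set_rhs) - set(dt.object_ids)
    if missing:
        raise ConfigError(f"support-set ids absent from table: {sorted(missing)}")
    supporters = set(stats.support_set_rhs)
    payload: dict[str, dict[str, list]] = {}
    for feature, _level in rule.conditions:
        col = dict(zip(dt.object_ids, dt.column(feature)))
        groups: dict[str, list] = {"supporting": [], "same_class": [], "other": []}
        ids: dict[str, list] = {"supporting": [], "same_class": [], "other": []}
        for oid, decision in zip(dt.object_ids, dt.decisions):
            if oid in supporters:
                g = "supporting"
            elif decision == rule.decision:
                g = "same_class"
            else:
                g = "other"
            groups[g].append(col[oid])
            ids[g].append(oid)
        payload[feature] = {
            "supporting": groups["supporting"],
            "same_class": groups["same_class"],
            "other": groups["other"],
            "supporting_ids": ids["supporting"],
            "same_class_ids": ids["same_class"],
            "other_ids": ids["other"],
        }
    return payload
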