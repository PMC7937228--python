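"""Rule induction and rule-level statistics.

A reduct overlaid on the equivalence classes of a decision table yields
IF-THEN rules: the class's feature values on the reduct form the
condition, each decision label present in the class forms a conclusion.
Every rule carries full statistics — LHS/RHS supports and support sets,
coverage, accuracy, a hypergeometric significance P value with
multiple-testing correction, and a risk-ratio block — and all of them
can be recalculated against any table sharing the vocabulary (used
after undersampling to re-anchor merged models on the original data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from scipy import stats as sps

from .discern import GENERALIZED_SEP, indiscernibility_partition
from .reducers import Reduct
from .tables import ConfigError, DecisionTable, DiscretizationMap

__all__ = [
    "Rule",
    "RuleStats",
    "RuleModel",
    "induce_rules",
    "rule_statistics",
    "rule_pvalue",
    "adjust_pvalues",
    "risk_ratio",
    "recalculate_rules",
    "write_rule_table",
]


@dataclass(frozen=True)
class Rule:
    """Conjunction of (feature = level) conditions with one conclusion."""

    conditions: tuple[tuple[str, str], ...]
    decision: str
    source_reduct: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule needs at least one conjunct")
        feats = [f for f, _ in self.conditions]
        if len(set(feats)) != len(feats):
            raise ValueError("duplicate feature in rule conditions")

    def key(self) -> tuple:
        """Identity for duplicate collapse: conditions + decision."""
        return (tuple(sorted(self.conditions)), self.decision)

    def __str__(self) -> str:
        lhs = " AND ".join(f"{f}={v}" for f, v in self.conditions)
        return f"IF {lhs} THEN {self.decision}"


@dataclass(frozen=True)
class RuleStats:
    support_lhs: int  # y: objects satisfying all conjuncts
    support_rhs: int  # x: those also matching the decision
    n_d: int  # objects in the rule's class
    n_o: int  # objects in all other classes
    n_total: int  # N
    coverage_rhs: float
    coverage_lhs: float
    accuracy: float
    support_set_lhs: tuple[str, ...]
    support_set_rhs: tuple[str, ...]
    vacuous: bool = False
    p_value: float = math.nan
    p_adjusted: float = math.nan
    risk_ratio: float = math.nan
    rr_ci_low: float = math.nan
    rr_ci_high: float = math.nan
    rr_p: float = math.nan
    rr_corrected: bool = False


@dataclass
class RuleModel:
    """Ordered rule collection plus the metadata needed to predict."""

    rules: list[tuple[Rule, RuleStats]]
    classes: tuple[str, ...]
    training_size: int
    discretization: DiscretizationMap | None = None
    adjust_method: str = "none"
    mean_submodel_accuracy: float | None = None

    @property
    def rules_per_class(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for rule, _ in self.rules:
            counts[rule.decision] = counts.get(rule.decision, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.rules)


def _sort_rules(
    rules: list[tuple[Rule, RuleStats]], classes: tuple[str, ...]
) -> list[tuple[Rule, RuleStats]]:
    class_pos = {c: i for i, c in enumerate(classes)}
    return sorted(
        rules,
        key=lambda rs: (
            class_pos.get(rs[0].decision, len(classes)),
            -rs[1].support_rhs,
            -rs[1].accuracy,
            tuple(sorted(rs[0].conditions)),
        ),
    )


def _match_mask(rule: Rule, dt: DecisionTable) -> list[bool]:
    cols = {f: dt.column(f) for f, _ in rule.conditions}
    return [
        all(cols[f][i] == v for f, v in rule.conditions)
        for i in range(dt.n_objects)
    ]


def _decision_matches(decision_label: str, rule_decision: str) -> bool:
    # a generalized label like "a|b" matches a rule for either class
    return rule_decision in decision_label.split(GENERALIZED_SEP)


def rule_statistics(rule: Rule, dt: DecisionTable) -> RuleStats:
    """Count supports and support sets of one rule on a table.

    y = objects satisfying the conditions, x = those with the rule's
    decision; accuracy x/y, RHS coverage x/n_d, LHS coverage y/n_d.
    A rule matching no object is flagged vacuous with accuracy 0.
    """
    for f, level in rule.conditions:
        dt.feature_index(f)  # raises ConfigError on unknown feature
    mask = _match_mask(rule, dt)
    lhs_ids = [oid for oid, m in zip(dt.object_ids, mask) if m]
    rhs_ids = [
        oid
        for oid, m, d in zip(dt.object_ids, mask, dt.decisions)
        if m and _decision_matches(d, rule.decision)
    ]
    y, x = len(lhs_ids), len(rhs_ids)
    n_total = dt.n_objects
    n_d = sum(1 for d in dt.decisions if _decision_matches(d, rule.decision))
    n_o = n_total - n_d
    vacuous = y == 0
    return RuleStats(
        support_lhs=y,
        support_rhs=x,
        n_d=n_d,
        n_o=n_o,
        n_total=n_total,
        coverage_rhs=x / n_d if n_d else 0.0,
        coverage_lhs=y / n_d if n_d else 0.0,
        accuracy=x / y if y else 0.0,
        support_set_lhs=tuple(lhs_ids),
        support_set_rhs=tuple(rhs_ids),
        vacuous=vacuous,
    )


def rule_pvalue(stats: RuleStats, tail: str = "upper") -> float:
    """Hypergeometric significance of the rule's RHS support.

    ``point`` returns P(X = x) = C(n_d,x) C(n_o,y-x) / C(N,y); ``upper``
    (the default significance measure) returns P(X >= x).
    """
    x, y, n_d, n_o, n = (
        stats.support_rhs,
        stats.support_lhs,
        stats.n_d,
        stats.n_o,
        stats.n_total,
    )
    if not (0 <= x <= y <= n and x <= n_d and y - x <= n_o and n_d + n_o == n):
        raise ConfigError("combinatorially impossible rule statistics")
    dist = sps.hypergeom(n, n_d, y)
    if tail == "point":
        return float(dist.pmf(x))
    if tail == "upper":
        return float(min(1.0, dist.sf(x - 1)))
    raise ConfigError(f"unknown tail {tail!r}")


def _adjust(pvals: list[float], method: str) -> list[float]:
    m = len(pvals)
    if method == "none" or m == 0:
        return list(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[i]))
            adj[i] = running
        return adj
    if method == "bh":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, min(1.0, pvals[i] * m / (rank + 1)))
            adj[i] = running
        return adj
    raise ConfigError(f"unknown adjustment method {method!r}")


def adjust_pvalues(model: RuleModel, method: str = "bonferroni") -> RuleModel:
    """Multiple-testing correction across all rules of the model."""
    pvals = [s.p_value for _, s in model.rules]
    if any(math.isnan(p) for p in pvals):
        raise ConfigError("raw p-values must be computed before adjustment")
    adjusted = _adjust(pvals, method)
    new_rules = [
        (r, replace(s, p_adjusted=a)) for (r, s), a in zip(model.rules, adjusted)
    ]
    return replace_model(model, rules=new_rules, adjust_method=method)


def replace_model(model: RuleModel, **kwargs) -> RuleModel:
    params = dict(
        rules=model.rules,
        classes=model.classes,
        training_size=model.training_size,
        discretization=model.discretization,
        adjust_method=model.adjust_method,
        mean_submodel_accuracy=model.mean_submodel_accuracy,
    )
    params.update(kwargs)
    return RuleModel(**params)


def risk_ratio(stats: RuleStats, conf_level: float = 0.95) -> RuleStats:
    """Risk ratio of the rule's class between LHS-satisfiers and the rest.

    Exposed group = objects matching the conditions (y of them, x with
    the outcome); unexposed = the other N-y objects, n_d-x with the
    outcome.  Wald CI on the log scale; zero cells get a 0.5 continuity
    correction (flagged).  Undefined (flagged NaN) when nobody is
    unexposed.
    """
    x, y, n_d, n = stats.support_rhs, stats.support_lhs, stats.n_d, stats.n_total
    if y == 0:
        return replace(stats, risk_ratio=math.nan, rr_ci_low=math.nan,
                       rr_ci_high=math.nan, rr_p=math.nan)
    if n == y:
        return replace(stats, risk_ratio=math.nan, rr_ci_low=math.nan,
                       rr_ci_high=math.nan, rr_p=math.nan)
    a, b = float(x), float(y)  # exposed: events / total
    c, d = float(n_d - x), float(n - y)  # unexposed: events / total
    corrected = False
    if a == 0 or c == 0 or a == b or c == d:
        a, b, c, d = a + 0.5, b + 1.0, c + 0.5, d + 1.0
        corrected = True
    rr = (a / b) / (c / d)
    se = math.sqrt(1.0 / a - 1.0 / b + 1.0 / c - 1.0 / d)
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    ci_low = math.exp(math.log(rr) - z * se)
    ci_high = math.exp(math.log(rr) + z * se)
    p = 2.0 * float(sps.norm.sf(abs(math.log(rr)) / se)) if se > 0 else 1.0
    return replace(
        stats,
        risk_ratio=rr,
        rr_ci_low=ci_low,
        rr_ci_high=ci_high,
        rr_p=min(1.0, p),
        rr_corrected=corrected,
    )


def _full_stats(rule: Rule, dt: DecisionTable, conf_level: float = 0.95) -> RuleStats:
    stats = rule_statistics(rule, dt)
    stats = replace(stats, p_value=rule_pvalue(stats, tail="upper"))
    return risk_ratio(stats, conf_level=conf_level)


def induce_rules(
    dt: DecisionTable,
    reducts: list[Reduct],
    adjust_method: str = "bonferroni",
    discretization: DiscretizationMap | None = None,
) -> RuleModel:
    """Overlay each reduct on the table's equivalence classes.

    Every block of IND(reduct) emits one rule per decision label present
    in it (boundary blocks spawn one rule per label).  Duplicate rules
    collapse; statistics are computed on ``dt`` and p-values adjusted
    across the whole model.
    """
    dt.require_discrete()
    if not reducts:
        warnings.warn("no reducts supplied: returning an empty model", stacklevel=2)
        return RuleModel(rules=[], classes=dt.classes, training_size=dt.n_objects,
                         discretization=discretization, adjust_method=adjust_method)
    order = {f: i for i, f in enumerate(dt.feature_names)}
    by_id = dict(zip(dt.object_ids, dt.decisions))
    pos = {oid: i for i, oid in enumerate(dt.object_ids)}
    seen: dict[tuple, Rule] = {}
    for reduct in reducts:
        feats = sorted(reduct.features, key=order.__getitem__)
        part = indiscernibility_partition(dt, feats)
        for block in part.blocks:
            rep = min(block, key=lambda o: pos[o])
            row = dt.values[pos[rep]]
            conditions = tuple((f, row[order[f]]) for f in feats)
            labels: dict[str, None] = {}
            for oid in sorted(block, key=lambda o: pos[o]):
                for lbl in by_id[oid].split(GENERALIZED_SEP):
                    labels.setdefault(lbl, None)
            for lbl in labels:
                rule = Rule(conditions=conditions, decision=lbl,
                            source_reduct=reduct.features)
                seen.setdefault(rule.key(), rule)
    rules = [(r, _full_stats(r, dt)) for r in seen.values()]
    # class order: expand generalized labels in appearance order
    classes: dict[str, None] = {}
    for d in dt.decisions:
        for lbl in d.split(GENERALIZED_SEP):
            classes.setdefault(lbl, None)
    model = RuleModel(
        rules=_sort_rules(rules, tuple(classes)),
        classes=tuple(classes),
        training_size=dt.n_objects,
        discretization=discretization,
    )
    return adjust_pvalues(model, adjust_method)


def recalculate_rules(model: RuleModel, dt: DecisionTable) -> RuleModel:
    """Recompute every rule's statistics against a reference table.

    Used after undersampling: the merged model's rules are re-anchored
    on the original training data.  Rules whose levels never occur stay
    in the model, flagged vacuous.
    """
    dt.require_discrete()
    for rule, _ in model.rules:
        for f, _level in rule.conditions:
            if f not in dt.feature_names:
                raise ConfigError(f"rule feature {f!r} absent from table")
    new_rules = [(r, _full_stats(r, dt)) for r, _ in model.rules]
    out = replace_model(
        model,
        rules=_sort_rules(new_rules, model.classes),
        training_size=dt.n_objects,
    )
    if model.adjust_method != "none":
        out = adjust_pvalues(out, model.adjust_method)
    return out


RULE_TABLE_COLUMNS = (
    "FEATURES", "LEVELS", "DECISION", "SUPP_LHS", "SUPP_RHS", "ACC_RHS",
    "COV_RHS", "COV_LHS", "PVAL", "PVAL_ADJ", "RR", "RR_CI_LOW",
    "RR_CI_HIGH", "RR_PVAL", "SUPPORT_SET_RHS",
)


def write_rule_table(model: RuleModel, path, delimiter: str = "\t") -> None:
    """Serialize the rule model in the delimited interchange format."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(RULE_TABLE_COLUMNS) + "\n")
        for rule, s in model.rules:
            row = (
                ",".join(f for f, _ in rule.conditions),
                ",".join(str(v) for _, v in rule.conditions),
                rule.decision,
                str(s.support_lhs),
                str(s.support_rhs),
                f"{s.accuracy:.6g}",
                f"{s.coverage_rhs:.6g}",
                f"{s.coverage_lhs:.6g}",
                f"{s.p_value:.6g}",
                f"{s.p_adjusted:.6g}",
                f"{s.risk_ratio:.6g}",
                f"{s.rr_ci_low:.6g}",
                f"{s.rr_ci_high:.6g}",
                f"{s.rr_p:.6g}",
                ";".join(s.support_set_rhs),
            )
            fh.write(delimiter.join(row) + "\n")
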