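"""Voting classification, cross-validation, undersampling, permutation.

Prediction feeds each object through the rule model and counts, per
class, the unique rules whose IF-part the object satisfies.  Because a
model can hold many more rules for one class than another, the raw
counts can be normalized by a class-level scalar before the argmax.
Training on imbalanced data is handled by an undersampling ensemble:
minority-sized majority draws, one model per balanced subset, merged to
the unique rules and recalculated on the full data.  Model-level
significance comes from a label-permutation test.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .discern import discernibility_family, enumerate_minimal_hitting_sets
from .reducers import GeneticParams, JohnsonParams, Reduct, genetic_reducts, johnson_reduct
from .rules import RuleModel, induce_rules, recalculate_rules, replace_model
from .tables import ConfigError, DecisionTable, apply_discretization, fit_equal_frequency

__all__ = [
    "VoteTally",
    "CvResult",
    "UndersampleConfig",
    "PipelineConfig",
    "PermutationResult",
    "UNCLASSIFIED",
    "predict",
    "train_model",
    "cross_validate",
    "undersample_train",
    "permutation_test",
]

UNCLASSIFIED = "<unclassified>"

NORMALIZATIONS = ("none", "mean", "median", "max", "rulnum", "rss")


@dataclass(frozen=True)
class VoteTally:
    object_id: str
    raw: dict[str, int]
    normalized: dict[str, float]
    predicted: str
    normalization: str
    tie: bool = False


@dataclass(frozen=True)
class CvResult:
    folds: tuple[tuple[float, Counter], ...]
    mean_accuracy: float
    pooled_accuracy: float
    auc: float
    seed: int
    fold_count: int
    positive_class: str


@dataclass(frozen=True)
class UndersampleConfig:
    n_sets: int | str = "auto"
    set_size: int | str = "auto"
    require_full_coverage: bool = True
    seed: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end training/evaluation settings."""

    reducer: str = "johnson"  # johnson | genetic | exhaustive
    bins: int = 3
    normalization: str = "none"
    adjust_method: str = "bonferroni"
    undersample: UndersampleConfig | None = None
    positive_class: str | None = None  # default: lexicographically last
    genetic: GeneticParams = field(default_factory=GeneticParams)

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.reducer not in ("johnson", "genetic", "exhaustive"):
            raise ConfigError(f"unknown reducer {self.reducer!r}")


@dataclass(frozen=True)
class PermutationResult:
    p_accuracy: float
    p_auc: float
    observed_accuracy: float
    observed_auc: float
    null_accuracy: tuple[float, ...]
    null_auc: tuple[float, ...]


def _normalizers(
    model: RuleModel, raw_by_class: dict[str, list[int]], method: str
) -> dict[str, float]:
    scalars: dict[str, float] = {}
    for cls in model.classes:
        counts = raw_by_class[cls]
        if method == "none":
            s = 1.0
        elif method == "mean":
            s = float(np.mean(counts))
        elif method == "median":
            s = float(np.median(counts))
        elif method == "max":
            s = float(np.max(counts))
        elif method == "rulnum":
            s = float(model.rules_per_class.get(cls, 0))
        elif method == "rss":
            s = math.sqrt(float(sum(c * c for c in counts)))
        else:
            raise ConfigError(f"unknown normalization {method!r}")
        scalars[cls] = s if s > 0 else 1.0
    return scalars


def predict(
    model: RuleModel, dt: DecisionTable, normalization: str = "none"
) -> list[VoteTally]:
    """Normalized rule voting: count firing rules per class, rescale,
    argmax.  Objects firing no rule are flagged ``UNCLASSIFIED``; exact
    ties go to the first class in training order with a tie flag.
    """
    dt.require_discrete()
    n = dt.n_objects
    raw = {cls: [0] * n for cls in model.classes}
    cols = {f: dt.column(f) for f in dt.feature_names}
    for rule, _stats in model.rules:
        try:
            cond_cols = [(cols[f], v) for f, v in rule.conditions]
        except KeyError as err:
            raise ConfigError(f"rule feature {err} absent from table") from None
        counts = raw[rule.decision]
        for i in range(n):
            if all(col[i] == v for col, v in cond_cols):
                counts[i] += 1
    scalars = _normalizers(model, raw, normalization)
    tallies = []
    for i, oid in enumerate(dt.object_ids):
        raw_i = {cls: raw[cls][i] for cls in model.classes}
        norm_i = {cls: raw_i[cls] / scalars[cls] for cls in model.classes}
        if all(v == 0 for v in raw_i.values()):
            predicted, tie = UNCLASSIFIED, False
        else:
            best = max(norm_i.values())
            winners = [cls for cls in model.classes if norm_i[cls] == best]
            predicted, tie = winners[0], len(winners) > 1
        tallies.append(
            VoteTally(object_id=oid, raw=raw_i, normalized=norm_i,
                      predicted=predicted, normalization=normalization, tie=tie)
        )
    return tallies


def _reducts_for(dt: DecisionTable, cfg: PipelineConfig, seed: int) -> list[Reduct]:
    fam = discernibility_family(dt)
    if not fam.clauses:
        return []
    if cfg.reducer == "johnson":
        return [johnson_reduct(fam, JohnsonParams())]
    if cfg.reducer == "genetic":
        return genetic_reducts(fam, replace(cfg.genetic, seed=seed))
    return [
        Reduct(features=r, method="exhaustive")
        for r in enumerate_minimal_hitting_sets(fam)
    ]


def train_model(dt: DecisionTable, cfg: PipelineConfig, seed: int = 1) -> RuleModel:
    """Reducts -> rules -> adjusted p-values on an all-discrete table."""
    dt.require_discrete()
    reducts = _reducts_for(dt, cfg, seed)
    if not reducts:
        warnings.warn(
            "degenerate training data (no discernible class structure): "
            "empty model", stacklevel=2,
        )
        return RuleModel(rules=[], classes=dt.classes,
                         training_size=dt.n_objects, adjust_method=cfg.adjust_method)
    return induce_rules(dt, reducts, adjust_method=cfg.adjust_method)


def undersample_train(
    dt: DecisionTable,
    us: UndersampleConfig,
    cfg: PipelineConfig,
    seed: int | None = None,
    evaluate_submodels: bool = True,
) -> RuleModel:
    """Balanced-subset ensemble: train one model per minority-sized
    sample of each larger class, merge the unique rules.

    Auto settings: subset majority draws are minority-sized, and enough
    subsets are made (``ceil(n_majority / n_minority)``) that, with
    ``require_full_coverage``, every majority object is drawn at least
    once.  The merged model's accuracy metadata is the mean of the
    sub-models' cross-validated accuracies on their balanced subsets
    (skipped when ``evaluate_submodels`` is off); callers should then
    recalculate the rule statistics on the full table.
    """
    dt.require_discrete()
    rng = np.random.default_rng(us.seed if seed is None else seed)
    class_counts = Counter(dt.decisions)
    if len(class_counts) < 2:
        raise ConfigError("undersampling needs at least two classes")
    minority = min(class_counts.values())
    set_size = minority if us.set_size == "auto" else int(us.set_size)
    if set_size > minority:
        raise ConfigError(
            f"set_size {set_size} exceeds the minority class size {minority}"
        )
    majority = max(class_counts.values())
    n_sets = (
        math.ceil(majority / set_size) if us.n_sets == "auto" else int(us.n_sets)
    )
    by_class: dict[str, list[int]] = {c: [] for c in class_counts}
    for i, d in enumerate(dt.decisions):
        by_class[d].append(i)

    # per larger class: permute once, deal out chunks so the union of
    # draws covers the class, then top up short chunks within-subset
    draws_per_class: dict[str, list[list[int]]] = {}
    for cls, members in by_class.items():
        if len(members) == set_size and us.set_size == "auto":
            draws_per_class[cls] = [list(members) for _ in range(n_sets)]
            continue
        perm = list(rng.permutation(members))
        if not us.require_full_coverage:
            perm_src = members
            draws = [
                list(rng.choice(perm_src, size=set_size, replace=False))
                for _ in range(n_sets)
            ]
            draws_per_class[cls] = draws
            continue
        draws = []
        for k in range(n_sets):
            chunk = perm[k * set_size:(k + 1) * set_size]
            if len(chunk) < set_size:
                pool = [m for m in members if m not in chunk]
                extra = list(rng.choice(pool, size=set_size - len(chunk),
                                        replace=False))
                chunk = chunk + extra
            draws.append(chunk)
        draws_per_class[cls] = draws

    merged: dict[tuple, tuple] = {}
    accuracies = []
    sub_cfg = replace(cfg, undersample=None)
    for k in range(n_sets):
        idx = sorted(i for cls in draws_per_class for i in draws_per_class[cls][k])
        sub = dt.subset_objects(idx)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_model = train_model(sub, cfg, seed=sub_seed)
        if evaluate_submodels:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cross_validate(sub, sub_cfg, folds=10, seed=sub_seed)
            accuracies.append(res.mean_accuracy)
        for rule, stats in sub_model.rules:
            merged.setdefault(rule.key(), (rule, stats))
    model = RuleModel(
        rules=list(merged.values()),
        classes=dt.classes,
        training_size=dt.n_objects,
        adjust_method=cfg.adjust_method,
        mean_submodel_accuracy=float(np.mean(accuracies)) if accuracies else None,
    )
    return model


def _fit_fold_model(train: DecisionTable, cfg: PipelineConfig, seed: int) -> RuleModel:
    if cfg.undersample is not None:
        model = undersample_train(train, cfg.undersample, cfg, seed=seed,
                                  evaluate_submodels=False)
        return recalculate_rules(model, train)
    return train_model(train, cfg, seed=seed)


def _stratified_folds(
    decisions: tuple[str, ...], folds: int, rng: np.random.Generator
) -> list[list[int]]:
    by_class: dict[str, list[int]] = {}
    for i, d in enumerate(decisions):
        by_class.setdefault(d, []).append(i)
    assignment: list[list[int]] = [[] for _ in range(folds)]
    for members in by_class.values():
        perm = rng.permutation(members)
        for j, idx in enumerate(perm):
            assignment[j % folds].append(int(idx))
    return [sorted(f) for f in assignment]


def cross_validate(
    dt: DecisionTable,
    cfg: PipelineConfig,
    folds: int = 10,
    seed: int = 1,
) -> CvResult:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: discretization cuts are fitted on the training part only,
    a model is trained (optionally via the undersampling ensemble) and
    the held-out objects are predicted.  Accuracy counts unclassified
    objects as errors; AUC pools the normalized votes for the positive
    class over all folds.
    """
    classes = dt.classes
    if len(classes) < 2:
        raise ConfigError("cross-validation needs at least two classes")
    min_class = min(Counter(dt.decisions).values())
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} objects; reducing folds "
            f"from {folds}", stacklevel=2,
        )
        folds = max(2, min_class)
    rng = np.random.default_rng(seed)
    fold_sets = _stratified_folds(dt.decisions, folds, rng)
    positive = cfg.positive_class or sorted(classes)[-1]
    fold_results = []
    pooled_correct = 0
    scores: list[float] = []
    truths: list[int] = []
    continuous = not dt.is_discrete()
    for test_idx in fold_sets:
        test_set = set(test_idx)
        train_idx = [i for i in range(dt.n_objects) if i not in test_set]
        train, test = dt.subset_objects(train_idx), dt.subset_objects(test_idx)
        if continuous:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dmap = fit_equal_frequency(train, cfg.bins)
            train = apply_discretization(train, dmap)
            test = apply_discretization(test, dmap)
        model = _fit_fold_model(train, cfg, seed=int(rng.integers(0, 2**31 - 1)))
        tallies = predict(model, test, cfg.normalization)
        confusion: Counter = Counter()
        correct = 0
        for tally, truth in zip(tallies, test.decisions):
            confusion[(truth, tally.predicted)] += 1
            if tally.predicted == truth:
                correct += 1
            scores.append(tally.normalized.get(positive, 0.0))
            truths.append(1 if truth == positive else 0)
        pooled_correct += correct
        fold_results.append((correct / len(test_idx), confusion))
    if len(set(truths)) < 2:
        auc = math.nan
    else:
        auc = float(roc_auc_score(truths, scores))
    return CvResult(
        folds=tuple(fold_results),
        mean_accuracy=float(np.mean([a for a, _ in fold_results])),
        pooled_accuracy=pooled_correct / dt.n_objects,
        auc=auc,
        seed=seed,
        fold_count=folds,
        positive_class=positive,
    )


def permutation_test(
    dt: DecisionTable,
    cfg: PipelineConfig,
    n_perm: int = 100,
    seed: int = 1,
    folds: int = 10,
) -> PermutationResult:
    """Label-shuffling significance of the cross-validated model.

    The decision labels are shuffled ``n_perm`` times, the whole
    pipeline is re-run on each shuffled table, and the add-one empirical
    p-value ``(1 + #{null >= observed}) / (1 + n_perm)`` is reported for
    accuracy and AUC separately (so p is never exactly zero).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    observed = cross_validate(dt, cfg, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    null_acc, null_auc = [], []
    for k in range(n_perm):
        shuffled = tuple(rng.permutation(dt.decisions))
        null_dt = replace(dt, decisions=shuffled)
        res = cross_validate(null_dt, cfg, folds=folds,
                             seed=int(rng.integers(0, 2**31 - 1)))
        null_acc.append(res.mean_accuracy)
        null_auc.append(res.auc)
    p_acc = (1 + sum(a >= observed.mean_accuracy for a in null_acc)) / (1 + n_perm)
    p_auc = (1 + sum(
        a >= observed.auc for a in null_auc if not math.isnan(a)
    )) / (1 + n_perm)
    return PermutationResult(
        p_accuracy=p_acc,
        p_auc=p_auc,
        observed_accuracy=observed.mean_accuracy,
        observed_auc=observed.auc,
        null_accuracy=tuple(null_acc),
        null_auc=tuple(null_auc),
    )
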