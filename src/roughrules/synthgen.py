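"""Synthetic decision tables with controlled covariance and signal.

Features are drawn as standard normals and multiplied by the transpose
of the lower-triangular Cholesky factor L of a requested
positive-definite covariance matrix D = L L^T, so rows carry exactly
the target covariance in expectation.  Class labels are assigned
deterministically by largest-remainder rounding of the requested
proportions; an optional mean shift on a subset of features makes one
class learnable with tunable effect size.
"""

from __future__ import annotations

import numpy as np

from .tables import (
    CONTINUOUS,
    ConfigError,
    DecisionTable,
    apply_discretization,
    fit_equal_frequency,
)

__all__ = ["SyntheticConfig", "synthesize", "build_covariance", "fixture_tables"]

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SyntheticConfig:
    n_objects: int
    n_features: int
    class_labels: tuple[str, ...] = ("control", "case")
    proportions: tuple[float, ...] = (0.5, 0.5)
    covariance: object = "identity"  # "identity" | ("exchangeable", rho) | matrix
    n_informative: int = 0
    effect_size: float = 0.0
    shift_class: str | None = None  # default: last class label
    discretize: int | None = None  # equal-frequency bin count
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_features < 1:
            raise ConfigError("need at least one object and one feature")
        if len(self.class_labels) != len(self.proportions):
            raise ConfigError("class labels and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ConfigError("class proportions must sum to 1")
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative exceeds n_features")


def build_covariance(spec, k: int) -> np.ndarray:
    """Materialize and validate a covariance spec as a k x k matrix."""
    if isinstance(spec, str):
        if spec != "identity":
            raise ConfigError(f"unknown covariance spec {spec!r}")
        cov = np.eye(k)
    elif isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "exchangeable":
        rho = float(spec[1])
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
    else:
        cov = np.asarray(spec, dtype=float)
        if cov.shape != (k, k):
            raise ConfigError(f"covariance must be {k}x{k}, got {cov.shape}")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ConfigError(
            f"covariance spec {spec!r} is not positive definite"
        ) from None
    return cov


def _largest_remainder_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    exact = [p * n for p in proportions]
    counts = [int(np.floor(e)) for e in exact]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: exact[i] - counts[i], reverse=True
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def synthesize(cfg: SyntheticConfig) -> DecisionTable:
    """Generate a decision table from the config; reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    cov = build_covariance(cfg.covariance, cfg.n_features)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((cfg.n_objects, cfg.n_features))
    x = z @ chol.T

    counts = _largest_remainder_counts(cfg.n_objects, cfg.proportions)
    decisions: list[str] = []
    for label, c in zip(cfg.class_labels, counts):
        decisions.extend([label] * c)

    if cfg.n_informative > 0 and cfg.effect_size != 0.0:
        target = cfg.shift_class or cfg.class_labels[-1]
        if target not in cfg.class_labels:
            raise ConfigError(f"shift_class {target!r} is not a class label")
        sd = np.sqrt(np.diag(cov))
        rows = [i for i, d in enumerate(decisions) if d == target]
        for j in range(cfg.n_informative):
            x[rows, j] += cfg.effect_size * sd[j]

    feature_names = tuple(f"f{j + 1}" for j in range(cfg.n_features))
    dt = DecisionTable(
        object_ids=tuple(str(i + 1) for i in range(cfg.n_objects)),
        feature_names=feature_names,
        values=tuple(tuple(float(v) for v in row) for row in x),
        decision_name="class",
        decisions=tuple(decisions),
        value_kind=tuple(CONTINUOUS for _ in feature_names),
    )
    if cfg.discretize is not None:
        dt = apply_discretization(dt, fit_equal_frequency(dt, cfg.discretize))
    return dt


def _discrete_table(ids, features, rows, decision_name, decisions) -> DecisionTable:
    return DecisionTable(
        object_ids=tuple(ids),
        feature_names=tuple(features),
        values=tuple(tuple(r) for r in rows),
        decision_name=decision_name,
        decisions=tuple(decisions),
        value_kind=tuple("discrete" for _ in features),
    )


def fixture_tables() -> dict[str, DecisionTable]:
    """Byte-stable toy tables used throughout the tests and docs.

    ``table1``: five objects, two genes with up/down levels, case/control
    diagnosis.  ``table2``: eight equivalence classes over three genes
    plus a risk factor; classes q4 and q5 sit in the boundary region and
    carry the generalized decision ``autism|control``.
    """
    table1 = _discrete_table(
        ids=("x1", "x2", "x3", "x4", "x5"),
        features=("gene1", "gene2"),
        rows=[
            ("up", "up"),
            ("up", "down"),
            ("up", "up"),
            ("down", "down"),
            ("down", "up"),
        ],
        decision_name="diagnosis",
        decisions=("case", "case", "control", "control", "case"),
    )
    table2 = _discrete_table(
        ids=("q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8"),
        features=("g1", "g2", "g3", "rf"),
        rows=[
            ("low", "low", "medium", "yes"),
            ("medium", "medium", "medium", "yes"),
            ("medium", "low", "medium", "yes"),
            ("medium", "low", "high", "no"),
            ("low", "low", "high", "no"),
            ("low", "high", "medium", "no"),
            ("medium", "high", "medium", "yes"),
            ("medium", "high", "high", "no"),
        ],
        decision_name="diagnosis",
        decisions=(
            "autism",
            "autism",
            "autism",
            "autism|control",
            "autism|control",
            "control",
            "control",
            "control",
        ),
    )
    return {"table1": table1, "table2": table2}
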