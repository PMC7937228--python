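# roughrules

Interpretable rule-based classification with rough sets. `roughrules`
learns transparent IF–THEN rule models from decision tables (rows =
objects, columns = features, one decision column), scores every rule
statistically, and keeps the whole pipeline inspectable end to end:

- **Discernibility & reducts** — indiscernibility partitions, rough
  lower/upper approximations, decision-relative discernibility clause
  families, and reduct computation three ways: exhaustive minimal
  hitting-set enumeration (the ground-truth oracle, capped at 20
  features), the deterministic Johnson greedy cover, and a seeded
  genetic-algorithm search whose fitness trades subset cost against
  clause-hitting fraction.
- **Rules with statistics** — every induced rule carries LHS/RHS
  supports and explicit support sets, coverage, accuracy, a
  hypergeometric upper-tail P value with Bonferroni/Holm/BH correction,
  and a risk-ratio block with Wald confidence intervals. All statistics
  can be recalculated against any table with the same vocabulary.
- **Classification** — normalized rule voting (`none`, `mean`,
  `median`, `max`, `rulnum`, `rss`), stratified cross-validation with
  accuracy and ROC AUC, undersampling ensembles for class-imbalanced
  data (balanced subsets, unique-rule merging, recalculation on the
  full table), and label-permutation model significance.
- **Synthetic data** — Gaussian feature matrices with a requested
  covariance (via its Cholesky factor), exact class proportions, and a
  tunable class-conditional mean shift for learnability experiments.
- **Network export** — per-class co-prediction networks (nodes =
  feature=level conjuncts, edge strength = Σ support × accuracy over
  significant rules) as edge-list TSV for standard graph tooling.

## CLI

```bash
# make a synthetic table (90/10 imbalance, 3 informative features)
roughrules synth data.csv --n-objects 200 --n-features 5 \
    --proportions 0.9,0.1 --n-informative 3 --effect-size 1.0 --seed 1

# cross-validate the default pipeline (Johnson reducer, 3 bins)
roughrules cv data.csv --folds 10 --seed 1

# train with undersampling and export the rule table
roughrules train data.csv --undersample --rules-out rules.tsv

# permutation significance of the model
roughrules permtest data.csv --n-perm 100 --folds 10

# co-prediction network of significant rules
roughrules export-net data.csv --edges-out edges.tsv
```

All subcommands accept `--reducer {johnson,genetic,exhaustive}`,
`--bins`, `--normalization`, `--adjust`, `--seed`, and the usual
delimiter/decision-column flags. Everything is reproducible for a fixed
seed.

## Library sketch

```python
from roughrules import (
    fixture_tables, discernibility_family, enumerate_minimal_hitting_sets,
    induce_rules, PipelineConfig, cross_validate,
)
from roughrules.reducers import Reduct

dt = fixture_tables()["table2"]
fam = discernibility_family(dt)
reducts = enumerate_minimal_hitting_sets(fam)   # [{g2, g3}, {g2, rf}]
model = induce_rules(dt, [Reduct(features=r, method="exhaustive") for r in reducts])
for rule, stats in model.rules:
    print(rule, stats.support_rhs, round(stats.accuracy, 2), stats.p_adjusted)
```

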