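# Methods

This note documents the procedures `nestpipe` implements, the choices
made where the design was genuinely open, and what the synthetic cohort
does and does not establish about real data.

## The nested cross-validation workflow

Model selection and performance estimation use different data. The
outer CV loop (k-fold, shuffle-split, or a single holdout) estimates
generalization; the inner loop, computed **only on outer-training
indices**, selects hyperparameters. Per outer fold the orchestrator:

1. scores a dummy baseline — always-majority-class for classification,
   always-training-mean for regression — so pipeline performance can be
   judged against a floor. With `use_test_set=True` the baseline is
   scored on the outer test split; with `use_test_set=False` it is
   scored on the outer-training split itself, because in that mode no
   computation may touch the test rows.
2. streams configurations from the optimizer (ask), evaluates each over
   the inner folds (fit on inner-train, metrics on both inner-train and
   inner-validation), and reports the mean validation value of the
   best-config metric back (tell).
3. selects the fold's best configuration direction-aware on that mean;
   ties go to the first configuration encountered in ask order, which
   makes runs reproducible and matches a strict-improvement comparison.
4. when `use_test_set=True`, refits the fold winner on the full
   outer-training split and scores the held-out test split.

The overall winner is the fold winner with the best test performance
(direction-aware on the best-config metric). This argmax couples the
choice of the *reported* configuration mildly to test data — it mirrors
the workflow's specification; the per-fold test metrics themselves
remain honest estimates. With `use_test_set=False` no test metrics
exist and the winner is the configuration with the best mean validation
performance across the folds where it completed evaluation. In both
modes the winner is finally refitted on **all** data (the deployable
model), and persisted when a project folder is configured.

Classification folds are stratified by class by default (`stratify=
False` disables it): at cohort sizes of a few hundred with a ~1:2 class
ratio, unstratified folds can degenerate to single-class validation
sets.

Failed configurations (an element raising during fit) are recorded with
the error string and excluded from selection; the run continues unless
every configuration failed. Configurations aborted by a performance
constraint keep the mean over their completed folds, are flagged
incomplete, and are excluded from selection — unless *no* configuration
completed, in which case selection falls back to the incomplete pool so
a heavily constrained run still yields a model.

## The pipeline contract

Elements declare capabilities (transform / predict / predict_proba /
target mutation / callback). During fit, each element is fitted and then
produces its successor's data: a transformer its transform, an estimator
its point predictions as one column (probabilities only inside a Stack
with `use_probabilities`), a target mutator a resampled
(features, targets, side-channel) triple — fit time only. At predict
time the flow is pure: mutators are the identity (rebalancing exists to
shape training distributions, not to alter what is scored), and
callbacks still fire so inspection covers both phases; their return
values are always discarded. Side-channel rows are subset and reordered
with the feature rows at every position, including through resamplers
(synthetic SMOTE rows inherit the side-channel row of their base
sample).

Composites obey two laws the test suite enforces bitwise: a Switch
behaves exactly as the pipeline with its active child inlined (inactive
children are never constructed), and each column block of a Stack equals
the corresponding child run standalone on the same input. Stacks forbid
row-count changes (hence resamplers) in children, and a stack is never a
valid final element — its concatenated features need a downstream
meta-learner. Branches are sub-pipelines usable anywhere an element is;
nesting is closed to arbitrary depth.

## Hyperparameter spaces and optimizers

Spaces are finite. Ranges with a `step` are half-open `[start, stop)`
arithmetic progressions; float ranges without a step expand to
`num_points` (default 10) values equally spaced on a linear or log10
axis *including both endpoints*. Nothing upstream fixes whether such
range endpoints should be inclusive; this convention is documented
behaviour chosen for least surprise, not an inherited fact. Enumeration
order is elements in pipeline order, domains in declared order, last
domain fastest-varying. `test_disabled` appends one extra configuration
that removes the element entirely.

Grid search enumerates exhaustively; random grid search draws
`min(n_configurations, |space|)` distinct points, seed-deterministically.
The *switch* optimizer requires the final pipeline position to be a
Switch and runs one sub-optimizer (random grid search by default) per
child over that child's individual space — the `n_configurations` budget
is per child, not total, so each learning algorithm gets equal
attention regardless of how large its space is. Adaptive strategies
(Bayesian, evolutionary) are intentionally out of core scope; the
ask/tell contract plus `register_optimizer` is the plug-in point, and
the engine guarantees exactly one tell per asked configuration.

Performance constraints stop unpromising configurations early. With
strategy `mean`, evaluation continues while the running mean of the
constraint metric is on the good side of the threshold; `first` tests
only the first fold's value; `any` aborts on any violating fold. For
error-type metrics the comparison flips.

## Metrics

All classification metrics come from confusion-count closed forms
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), balanced accuracy
their mean, F1 = 2TP/(2TP+FP+FN), MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)
(TN+FP)(TN+FN))). A zero denominator scores 0 with a degeneracy flag
rather than NaN, keeping the configuration ranking a total order. For
0/1-coded labels class 1 is always the positive class, even when a fold
contains only one class. Multiclass inputs are handled by macro
averaging (MCC by its generalized correlation form) — an extension
beyond the binary problems the framework is primarily aimed at.

## Built-in elements

The resamplers implement the three standard rebalancing schemes
directly: uniform random deletion of majority rows, uniform random
duplication of minority rows, and SMOTE — each synthetic sample is drawn
uniformly on the segment between a random minority row and one of its
k=5 nearest minority neighbours (Euclidean; k is the field's customary
default). Output order is original rows first, then synthesized rows.
SMOTE is implemented as pure minority oversampling — the conventional
definition — and falls back to duplication with a warning when fewer
than two minority samples exist.

`LassoFeatureSelection` fits an L1-penalized linear model (scikit-learn's
coordinate-descent Lasso, tolerance 1e-6, max 10,000 iterations) on
internally standardized inputs, ranks features by |coefficient| and
keeps the top ⌈percentile·p⌉ (percentile a fraction in (0, 1]); the
column mask is stored at fit and reused verbatim at transform. If every
coefficient is zero (penalty too strong), the first ⌈percentile·p⌉
columns are kept with a warning rather than failing the run.

The reference learners (constant / majority / nearest-centroid
classifiers, mean regressor, standardizing scaler, mean imputer) are
dependency-free and deterministic; they exist so the whole framework —
and its test suite — exercises real data flow without heavyweight
models. Scikit-learn algorithms ('StandardScaler', 'PCA',
'RandomForestClassifier', ...) are pre-registered as host-environment
entries resolved lazily at construction.

## Caching, persistence, result logs

The transform cache keys on a digest of (dataset content fingerprint,
fold training indices, element position, keyword + fixed parameters,
configuration of the element and everything upstream) and stores the
fitted element together with its output, so grids with shared
preprocessing prefixes compute each prefix once per fold. Correctness
dominates speed: the fingerprint hashes the raw feature/target bytes.
Cached and cache-free runs are bitwise identical; elements using
randomness are cacheable only if their seed is part of their fixed
parameters. Corrupt entries are recomputed and overwritten with a
warning.

`.photon` archives are zip files holding a JSON manifest (schema
version, pipeline structure, winning configuration, feature names), the
pickled fitted state, and a SHA-256 checksum verified at load; element
keywords are checked against the registry before unpickling and a
missing keyword is reported by name. The format is versioned and
self-describing; byte-level compatibility with any other tool's archive
format is a non-goal. Loading an archive in a fresh process reproduces
predictions bitwise.

Result trees serialize to a stable JSON schema (version-checked on
read; unknown future fields are ignored) containing per-fold indices,
the baseline, every tested configuration with per-inner-fold
train/validation metrics, per-fold winners and test metrics, and the
overall winner. Computation times are recorded for inspection but
excluded from every equality assertion — they are hardware, not model.

## The synthetic cohort

The generator emulates a small clinical prediction dataset: 299
samples, 12 features, ~32% positive class by default. Informative
features are class-shifted Gaussians (shift = `effect_size`, default
1.0 — clearly learnable, not trivial; 4 informative columns by
default), one informative column is a binary "comorbidity-like" marker
(prevalence 0.7 in positives vs 0.3 in negatives), the rest is pure
noise, and missingness is injected completely at random. Everything is
seed-deterministic and a descriptor reports the ground truth.

What it does *not* emulate: correlated features, non-Gaussian
marginals, informative missingness, label noise, or covariate shift.
Passing tests on this cohort therefore establish that the machinery is
correct (no leakage, correct selection, exact metric arithmetic), not
that any particular algorithm will perform comparably on real clinical
tables.

Two sentinels anchor the suite: with effect size 2 the Bayes-appropriate
switch child must win in ≥95% of seeded replicates, and with effect
size 0 the selected configuration's mean validation balanced accuracy
must stay in [0.4, 0.6] — an implementation that leaks validation rows
into fits inflates the latter and fails loudly.

## Problem sizes

The test suite and `scripts/acceptance.py` run on deliberately small
instances — cohorts of ≤299 rows, grids of ≤24 configurations, 2–3
outer × 2–3 inner folds, 10–20 seeded replicates — chosen so the whole
verification is quick on a single CPU while still exercising every code
path (composites to depth 3, constraints, caching, persistence).

## Known limitations

- No probabilistic metrics (AUROC, log-loss) and no sample weights.
- No conditional hyperparameters beyond switch membership.
- Outer folds execute sequentially; results are independent of
  execution order by construction, but no distributed runtime ships.
- No automatic ensemble aggregation for terminal stacks.
- Callbacks holding closures (lambdas) cannot be pickled into `.photon`
  archives; use module-level delegates for models that must persist.
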