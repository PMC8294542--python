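"""Nested cross-validated training, optimization and testing.

The orchestrator runs the canonical nested scheme: an outer loop
estimates generalization performance while an inner loop — run strictly
on outer-training data — selects hyperparameters.  Per outer fold it

1. establishes a dummy baseline (majority class / training mean);
2. initializes the optimizer on the pipeline's joint configuration space;
3. evaluates every asked configuration over the inner folds (fit on
   inner-train, metrics on inner-train and inner-validation), reports the
   mean validation performance back to the optimizer, and honours any
   performance constraints (aborted configurations keep the mean over
   their completed folds but are flagged incomplete and excluded from
   selection while complete competitors exist);
4. selects the fold's best configuration by mean validation performance
   on the best-config metric (direction-aware; first encountered wins
   ties) and — when ``use_test_set`` — refits it on the full outer-train
   split and evaluates the held-out test split.

After all folds the overall winner is the best configuration of the
outer fold with the best test performance (``use_test_set=True``) or the
configuration with the best mean validation performance across the folds
where it was evaluated (``use_test_set=False``; no test metrics are
reported in that mode).  The winner is finally refitted on all data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .hyperspace import Config, DefinitionError
from .metrics import Direction, METRIC_NAMES, direction as metric_direction, score
from .optimization import (
    MinimumPerformanceConstraint,
    OptimizerSpec,
    make_optimizer,
    should_continue,
)
from .pipeline import DataTriple, Pipeline, PipelineError
from .results_io import (
    Cache,
    ConfigEvaluation,
    InnerFoldRecord,
    OuterFoldResult,
    ResultTree,
    dataset_fingerprint,
    save_model,
    write_results,
)

__all__ = [
    "CVScheme",
    "FoldPlan",
    "OuterFold",
    "WorkflowSpec",
    "WorkflowError",
    "build_fold_plan",
    "dummy_baseline",
    "run",
    "get_mean_of_best_validation_configs_per_estimator",
]


class WorkflowError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Cross-validation schemes and fold plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVScheme:
    """A cross-validation scheme: k-fold, shuffle-split, or a single
    holdout split.  Deterministic under its seed."""

    kind: str  # k_fold | shuffle_split | holdout
    n_splits: int = 5
    test_size: float = 0.2
    shuffle: bool = False
    seed: Optional[int] = 0

    def __post_init__(self):
        if self.kind not in ("k_fold", "shuffle_split", "holdout"):
            raise DefinitionError(f"unknown cv scheme {self.kind!r}")
        if self.kind == "k_fold" and self.n_splits < 2:
            raise DefinitionError("k_fold needs n_splits >= 2")
        if self.kind in ("shuffle_split", "holdout") and not 0 < self.test_size < 1:
            raise DefinitionError("test_size must lie in (0, 1)")

    @classmethod
    def k_fold(cls, n_splits=5, shuffle=False, seed=0):
        return cls("k_fold", n_splits=n_splits, shuffle=shuffle, seed=seed)

    @classmethod
    def shuffle_split(cls, n_splits=5, test_size=0.2, seed=0):
        return cls("shuffle_split", n_splits=n_splits, test_size=test_size, seed=seed)

    @classmethod
    def holdout(cls, test_size=0.2, seed=0):
        return cls("holdout", n_splits=1, test_size=test_size, seed=seed)

    def split(self, indices: np.ndarray, stratify: Optional[np.ndarray] = None):
        """Yield (train, eval) pairs of *absolute* indices."""
        from sklearn.model_selection import (
            KFold,
            ShuffleSplit,
            StratifiedKFold,
            StratifiedShuffleSplit,
        )

        indices = np.asarray(indices)
        X_dummy = np.zeros((len(indices), 1))
        if self.kind == "k_fold":
            cls = KFold if stratify is None else StratifiedKFold
            cv = cls(n_splits=self.n_splits, shuffle=self.shuffle,
                     random_state=self.seed if self.shuffle else None)
        else:
            n_splits = 1 if self.kind == "holdout" else self.n_splits
            cls = ShuffleSplit if stratify is None else StratifiedShuffleSplit
            cv = cls(n_splits=n_splits, test_size=self.test_size, random_state=self.seed)
        for tr, ev in cv.split(X_dummy, stratify):
            yield indices[tr], indices[ev]

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_splits": self.n_splits,
                "test_size": self.test_size, "shuffle": self.shuffle, "seed": self.seed}


@dataclass
class OuterFold:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    inner_folds: list  # [(train, validation)] absolute indices, within outer-train


@dataclass
class FoldPlan:
    outer_folds: list


def build_fold_plan(n_samples: int, outer_cv: CVScheme, inner_cv: CVScheme,
                    stratify_targets: Optional[np.ndarray] = None) -> FoldPlan:
    """Outer splits over all samples; inner splits computed per outer fold
    on the outer-training indices only (the no-leakage backbone)."""
    idx = np.arange(n_samples)
    strat = None if stratify_targets is None else np.asarray(stratify_targets)
    outer = []
    for fid, (tr, te) in enumerate(outer_cv.split(idx, strat)):
        inner_strat = None if strat is None else strat[tr]
        inner = [(itr, ival) for itr, ival in inner_cv.split(tr, inner_strat)]
        outer.append(OuterFold(fid, tr, te, inner))
    return FoldPlan(outer)


# ---------------------------------------------------------------------------
# Workflow specification
# ---------------------------------------------------------------------------


@dataclass
class WorkflowSpec:
    """Everything that parameterizes a training/optimization/testing run."""

    name: str
    outer_cv: CVScheme
    inner_cv: CVScheme
    metrics: Sequence[str]
    best_config_metric: str
    optimizer: OptimizerSpec = field(default_factory=OptimizerSpec)
    constraints: Sequence[MinimumPerformanceConstraint] = field(default_factory=list)
    use_test_set: bool = True
    task: str = "classification"
    project_folder: Optional[str] = None
    cache_folder: Optional[str] = None
    verbosity: int = 0
    stratify: bool = True

    def __post_init__(self):
        self.metrics = list(self.metrics)
        if not self.metrics:
            raise DefinitionError("at least one metric is required")
        for m in self.metrics:
            if m not in METRIC_NAMES:
                raise DefinitionError(f"unknown metric {m!r}")
        if self.best_config_metric not in self.metrics:
            raise DefinitionError(
                f"best_config_metric {self.best_config_metric!r} must be among "
                f"the computed metrics {self.metrics}")
        if self.task not in ("classification", "regression"):
            raise DefinitionError(f"unknown task {self.task!r}")
        if isinstance(self.constraints, MinimumPerformanceConstraint):
            self.constraints = [self.constraints]
        self.constraints = list(self.constraints)
        for c in self.constraints:
            if c.metric_name not in self.metrics:
                raise DefinitionError(
                    f"constraint metric {c.metric_name!r} is not computed")
        if not 0 <= self.verbosity <= 2:
            raise DefinitionError("verbosity must be 0, 1 or 2")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "outer_cv": self.outer_cv.to_dict(),
            "inner_cv": self.inner_cv.to_dict(),
            "metrics": list(self.metrics),
            "best_config_metric": self.best_config_metric,
            "optimizer": {
                "name": self.optimizer.name,
                "n_configurations": self.optimizer.n_configurations,
                "inner_name": self.optimizer.inner_name,
                "rng_seed": self.optimizer.rng_seed,
            },
            "constraints": [
                {"metric": c.metric_name, "threshold": c.threshold,
                 "strategy": c.strategy}
                for c in self.constraints
            ],
            "use_test_set": self.use_test_set,
            "task": self.task,
            "stratify": self.stratify,
        }


# ---------------------------------------------------------------------------
# Dummy baseline
# ---------------------------------------------------------------------------


def dummy_baseline(train_targets, eval_targets, task: str,
                   metrics: Sequence[str]) -> dict:
    """Performance of the trivial heuristic — always the majority training
    class (classification) or the training mean (regression) — on the
    evaluation targets."""
    yt = np.asarray(train_targets)
    ye = np.asarray(eval_targets)
    if task == "classification":
        classes, counts = np.unique(yt, return_counts=True)
        pred = np.full(len(ye), classes[int(np.argmax(counts))])
    else:
        pred = np.full(len(ye), float(np.mean(yt.astype(float))))
    return {m: score(m, ye, pred) for m in metrics}


# ---------------------------------------------------------------------------
# Ranking helpers
# ---------------------------------------------------------------------------


def _better(a: float, b: Optional[float], d: Direction) -> bool:
    """Is a strictly better than b (b=None means no incumbent)?"""
    if b is None:
        return True
    return a > b if d is Direction.GREATER_IS_BETTER else a < b


def _select_best(evaluations: list, d: Direction) -> Optional[ConfigEvaluation]:
    """Direction-aware best by val_performance; complete configurations
    outrank incomplete ones; first encountered wins ties."""
    for pool in (
        [e for e in evaluations if not e.failed and not e.incomplete],
        [e for e in evaluations if not e.failed and e.val_performance is not None],
    ):
        best = None
        for e in pool:
            if best is None or _better(e.val_performance, best.val_performance, d):
                best = e
        if best is not None:
            return best
    return None


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def _evaluate_config(pipeline: Pipeline, config: Config, data: DataTriple,
                     inner_folds, spec: WorkflowSpec, cache, fingerprint,
                     ) -> ConfigEvaluation:
    ev = ConfigEvaluation(config=config)
    constraint_vals: dict[int, list[float]] = {i: [] for i in range(len(spec.constraints))}
    best_metric_vals: list[float] = []
    t0 = time.perf_counter()
    try:
        for fid, (tr, val) in enumerate(inner_folds):
            ctx = None
            if cache is not None:
                ctx = {"fingerprint": fingerprint, "train_indices": tr}
            fitted = pipeline.fit(data.subset(tr), config, cache=cache, cache_ctx=ctx)
            pred_tr = fitted.predict(data.features[tr],
                                     None if data.side_channel is None
                                     else data.side_channel.iloc[tr])
            pred_val = fitted.predict(data.features[val],
                                      None if data.side_channel is None
                                      else data.side_channel.iloc[val])
            rec = InnerFoldRecord(
                fold_id=fid,
                train_indices=list(map(int, tr)),
                validation_indices=list(map(int, val)),
                train_metrics={m: score(m, data.targets[tr], pred_tr)
                               for m in spec.metrics},
                validation_metrics={m: score(m, data.targets[val], pred_val)
                                    for m in spec.metrics},
            )
            ev.inner_folds.append(rec)
            ev.completed_folds += 1
            best_metric_vals.append(rec.validation_metrics[spec.best_config_metric])
            stop = False
            for i, constraint in enumerate(spec.constraints):
                constraint_vals[i].append(
                    rec.validation_metrics[constraint.metric_name])
                if not should_continue(constraint_vals[i], constraint):
                    stop = True
            if stop:
                ev.incomplete = ev.completed_folds < len(inner_folds)
                break
    except (PipelineError, DefinitionError) as exc:
        ev.failed = True
        ev.error = str(exc)
    ev.computation_time = time.perf_counter() - t0
    if best_metric_vals:
        ev.val_performance = float(np.mean(best_metric_vals))
    return ev


def run(spec: WorkflowSpec, pipeline: Pipeline | Sequence,
        data: DataTriple) -> tuple[ResultTree, object]:
    """Execute the full nested training/optimization/testing workflow.

    Returns the populated result tree and the final pipeline refitted with
    the overall best configuration on all data.
    """
    if not isinstance(pipeline, Pipeline):
        pipeline = Pipeline(pipeline)
    if data.targets is None:
        raise DefinitionError("the workflow requires targets")
    space = pipeline.space()
    d = metric_direction(spec.best_config_metric)
    stratify = data.targets if (spec.task == "classification" and spec.stratify) else None
    plan = build_fold_plan(data.n, spec.outer_cv, spec.inner_cv, stratify)
    cache = Cache(spec.cache_folder) if spec.cache_folder else None
    fingerprint = dataset_fingerprint(data) if cache is not None else None

    tree = ResultTree(
        name=spec.name,
        best_config_metric=spec.best_config_metric,
        metrics=list(spec.metrics),
        spec_echo=spec.to_dict(),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    for fold in plan.outer_folds:
        tr, te = fold.train_indices, fold.test_indices
        baseline_eval = te if spec.use_test_set else tr
        result = OuterFoldResult(
            fold_id=fold.fold_id,
            train_indices=list(map(int, tr)),
            test_indices=list(map(int, te)),
            baseline=dummy_baseline(data.targets[tr], data.targets[baseline_eval],
                                    spec.task, spec.metrics),
        )
        optimizer = make_optimizer(spec.optimizer, space)
        for config in optimizer.ask():
            ev = _evaluate_config(pipeline, config, data, fold.inner_folds,
                                  spec, cache, fingerprint)
            optimizer.tell(config, np.nan if ev.val_performance is None
                           else ev.val_performance)
            result.tested_configs.append(ev)
            if spec.verbosity >= 1:
                status = "failed" if ev.failed else (
                    "aborted" if ev.incomplete else "ok")
                print(f"[{spec.name}] outer fold {fold.fold_id} | "
                      f"{spec.best_config_metric}={ev.val_performance} "
                      f"({status}) | config {config.to_dict()['assignments']}")

        best = _select_best(result.tested_configs, d)
        if best is None:
            raise WorkflowError(
                f"outer fold {fold.fold_id}: every tested configuration failed")
        result.best_config = best.config

        if spec.use_test_set:
            ctx = ({"fingerprint": fingerprint, "train_indices": tr}
                   if cache is not None else None)
            fitted = pipeline.fit(data.subset(tr), best.config,
                                  cache=cache, cache_ctx=ctx)
            pred_tr = fitted.predict(data.features[tr],
                                     None if data.side_channel is None
                                     else data.side_channel.iloc[tr])
            pred_te = fitted.predict(data.features[te],
                                     None if data.side_channel is None
                                     else data.side_channel.iloc[te])
            result.train_metrics = {m: score(m, data.targets[tr], pred_tr)
                                    for m in spec.metrics}
            result.test_metrics = {m: score(m, data.targets[te], pred_te)
                                   for m in spec.metrics}
        tree.outer_folds.append(result)

    tree.overall_best_config = _overall_best(tree, d, spec.use_test_set)

    # unconditional final refit on all data
    ctx = ({"fingerprint": fingerprint, "train_indices": np.arange(data.n)}
           if cache is not None else None)
    final = pipeline.fit(data, tree.overall_best_config, cache=cache, cache_ctx=ctx)

    if spec.project_folder:
        folder = Path(spec.project_folder)
        folder.mkdir(parents=True, exist_ok=True)
        write_results(tree, folder / f"{spec.name}_results.json")
        save_model(final, folder / f"{spec.name}_model.photon")
    return tree, final


def _overall_best(tree: ResultTree, d: Direction, use_test_set: bool) -> Config:
    if use_test_set:
        best_fold, best_val = None, None
        for f in tree.outer_folds:
            v = f.test_metrics.get(tree.best_config_metric)
            if v is not None and (best_val is None or _better(v, best_val, d)):
                best_fold, best_val = f, v
        if best_fold is None:
            raise WorkflowError("no outer fold produced test metrics")
        return best_fold.best_config
    # mean validation performance per configuration across the folds where
    # it was evaluated (complete, non-failed evaluations only)
    by_key: dict = {}
    order: list = []
    for f in tree.outer_folds:
        for ev in f.tested_configs:
            if ev.failed or ev.incomplete or ev.val_performance is None:
                continue
            k = ev.config.key()
            if k not in by_key:
                by_key[k] = (ev.config, [])
                order.append(k)
            by_key[k][1].append(ev.val_performance)
    best_cfg, best_val = None, None
    for k in order:
        cfg, vals = by_key[k]
        mean = float(np.mean(vals))
        if best_cfg is None or _better(mean, best_val, d):
            best_cfg, best_val = cfg, mean
    if best_cfg is None:
        raise WorkflowError("no configuration completed evaluation")
    return best_cfg


# ---------------------------------------------------------------------------
# Per-estimator summary (switch pipelines)
# ---------------------------------------------------------------------------


def get_mean_of_best_validation_configs_per_estimator(
        tree: ResultTree, switch_name: Optional[str] = None) -> dict:
    """For each child of the pipeline's switch: take its best configuration
    per outer fold (by validation performance on the best-config metric)
    and average each validation metric across outer folds.

    Returns ``{child_keyword: {metric: mean}}``.
    """
    switch_paths = set()
    for f in tree.outer_folds:
        for ev in f.tested_configs:
            switch_paths.update(ev.config.active_switch_children)
    if not switch_paths:
        raise WorkflowError("the pipeline contains no switch element")
    if switch_name is None:
        if len(switch_paths) > 1:
            raise WorkflowError(
                f"multiple switches present ({sorted(switch_paths)}); "
                "pass switch_name")
        switch_name = next(iter(switch_paths))
    elif switch_name not in switch_paths:
        raise WorkflowError(f"no switch named {switch_name!r} in the results")

    d = metric_direction(tree.best_config_metric)
    per_child: dict = {}
    for f in tree.outer_folds:
        fold_best: dict = {}
        for ev in f.tested_configs:
            child = ev.config.active_switch_children.get(switch_name)
            if child is None or ev.failed or ev.val_performance is None:
                continue
            inc = fold_best.get(child)
            if inc is None or _better(ev.val_performance, inc.val_performance, d):
                fold_best[child] = ev
        for child, ev in fold_best.items():
            per_child.setdefault(child, []).append(ev.mean_validation_metrics())
    return {
        child: {m: float(np.mean([fm[m] for fm in fold_metrics]))
                for m in fold_metrics[0]}
        for child, fold_metrics in per_child.items()
    }
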