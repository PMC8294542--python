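"""Nested-CV orchestration: oracle equivalence, leakage, determinism."""

import numpy as np
import pytest

from nestpipe import (
    Config,
    CVScheme,
    DataTriple,
    MinimumPerformanceConstraint,
    OptimizerSpec,
    Pipeline,
    PipelineElement,
    Switch,
    WorkflowError,
    WorkflowSpec,
    build_fold_plan,
    dummy_baseline,
    get_mean_of_best_validation_configs_per_estimator,
    run,
)
from nestpipe.results_io import (
    ConfigEvaluation,
    InnerFoldRecord,
    OuterFoldResult,
    ResultTree,
)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------


class TestFoldPlan:
    def test_k_fold_partitions_sample_set(self):
        plan = build_fold_plan(10, CVScheme.k_fold(5), CVScheme.k_fold(2))
        tests = [set(f.test_indices) for f in plan.outer_folds]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not tests[a] & tests[b]

    def test_shuffle_split_sizes(self):
        plan = build_fold_plan(10, CVScheme.shuffle_split(3, test_size=0.2, seed=0),
                               CVScheme.k_fold(2))
        assert len(plan.outer_folds) == 3
        assert all(len(f.test_indices) == 2 for f in plan.outer_folds)

    def test_inner_indices_subset_of_outer_train(self):
        y = np.array([0, 1] * 15)
        plan = build_fold_plan(30, CVScheme.k_fold(3), CVScheme.k_fold(2), y)
        for f in plan.outer_folds:
            train = set(f.train_indices)
            for itr, ival in f.inner_folds:
                assert set(itr) <= train and set(ival) <= train
                assert not set(itr) & set(ival)

    def test_deterministic_under_seed(self):
        a = build_fold_plan(20, CVScheme.shuffle_split(2, seed=3), CVScheme.k_fold(2))
        b = build_fold_plan(20, CVScheme.shuffle_split(2, seed=3), CVScheme.k_fold(2))
        for fa, fb in zip(a.outer_folds, b.outer_folds):
            assert np.array_equal(fa.train_indices, fb.train_indices)
            assert np.array_equal(fa.test_indices, fb.test_indices)


class TestDummyBaseline:
    def test_majority_rate_on_imbalanced_targets(self):
        rng = np.random.default_rng(0)
        train = (rng.random(500) < 0.32).astype(int)  # ~68% class 0
        evalu = (rng.random(500) < 0.32).astype(int)
        out = dummy_baseline(train, evalu, "classification", ["accuracy"])
        assert out["accuracy"] == pytest.approx(1 - evalu.mean(), abs=1e-12)
        assert out["accuracy"] == pytest.approx(0.68, abs=0.05)

    def test_majority_balanced_accuracy_is_half(self):
        train = np.array([0, 0, 0, 1])
        evalu = np.array([0, 0, 1, 1])
        out = dummy_baseline(train, evalu, "classification", ["balanced_accuracy"])
        assert out["balanced_accuracy"] == pytest.approx(0.5)

    def test_regression_constant_targets_zero_mse(self):
        out = dummy_baseline([2.0, 2.0], [2.0, 2.0, 2.0], "regression",
                             ["mean_squared_error"])
        assert out["mean_squared_error"] == 0.0


# ---------------------------------------------------------------------------
# Oracle equivalence on a fixed toy problem
# ---------------------------------------------------------------------------


def toy_data(n=40, seed=13):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 2))
    X[:, 0] += 1.5 * y  # informative column
    return DataTriple(X, y)


FACTORS = [0.5, 1.0]
THRESHOLDS = [0.0, 0.5, 1.0, 1.5]


def toy_pipeline():
    return Pipeline([
        PipelineElement("ScaleBy", hyperparameters={"factor": FACTORS}, name="scale"),
        PipelineElement("ThresholdClassifier",
                        hyperparameters={"threshold": THRESHOLDS}, name="clf"),
    ])


def toy_spec(**over):
    kw = dict(
        name="toy",
        outer_cv=CVScheme.k_fold(2, shuffle=True, seed=1),
        inner_cv=CVScheme.k_fold(2, shuffle=True, seed=2),
        metrics=["accuracy", "balanced_accuracy", "f1_score"],
        best_config_metric="accuracy",
        optimizer=OptimizerSpec(name="grid_search"),
        use_test_set=True,
    )
    kw.update(over)
    return WorkflowSpec(**kw)


def straight_line_nested_cv(X, y):
    """Independent nested-CV oracle: plain loops over sklearn splitters and
    hand-applied arithmetic for the same deterministic toy learners."""
    from sklearn.model_selection import StratifiedKFold

    from nestpipe.metrics import score

    def predict(Xm, factor, threshold):
        return ((Xm * factor).sum(axis=1) > threshold).astype(int)

    results = []
    okf = StratifiedKFold(2, shuffle=True, random_state=1)
    for tr, te in okf.split(np.zeros((len(y), 1)), y):
        ikf = StratifiedKFold(2, shuffle=True, random_state=2)
        inner = [(tr[a], tr[b])
                 for a, b in ikf.split(np.zeros((len(tr), 1)), y[tr])]
        best = None  # (val_acc, factor, threshold)
        config_vals = {}
        for f in FACTORS:          # element order: scale, then clf
            for t in THRESHOLDS:   # last domain varies fastest
                accs = [score("accuracy", y[ival], predict(X[ival], f, t))
                        for itr, ival in inner]
                val = float(np.mean(accs))
                config_vals[(f, t)] = val
                if best is None or val > best[0]:
                    best = (val, f, t)
        _, f, t = best
        test_metrics = {m: score(m, y[te], predict(X[te], f, t))
                        for m in ("accuracy", "balanced_accuracy", "f1_score")}
        results.append({"best": (f, t), "val": best[0], "test": test_metrics,
                        "config_vals": config_vals})
    # overall winner: fold with best test accuracy (first wins ties)
    best_fold = max(range(len(results)),
                    key=lambda i: (results[i]["test"]["accuracy"], -i))
    return results, results[best_fold]["best"]


class TestOracleEquivalence:
    def test_run_matches_straight_line_script(self):
        data = toy_data()
        tree, final = run(toy_spec(), toy_pipeline(), data)
        oracle, overall = straight_line_nested_cv(data.features, data.targets)

        assert len(tree.outer_folds) == 2
        for fold, orc in zip(tree.outer_folds, oracle):
            got = (fold.best_config.assignments["scale__factor"],
                   fold.best_config.assignments["clf__threshold"])
            assert got == orc["best"]
            best_ev = next(e for e in fold.tested_configs
                           if e.config == fold.best_config)
            assert best_ev.val_performance == pytest.approx(orc["val"], abs=1e-12)
            for m, v in orc["test"].items():
                assert fold.test_metrics[m] == pytest.approx(v, abs=1e-12)
            # every tested configuration's validation mean matches
            for ev in fold.tested_configs:
                key = (ev.config.assignments["scale__factor"],
                       ev.config.assignments["clf__threshold"])
                assert ev.val_performance == pytest.approx(
                    orc["config_vals"][key], abs=1e-12)
        got_overall = (tree.overall_best_config.assignments["scale__factor"],
                       tree.overall_best_config.assignments["clf__threshold"])
        assert got_overall == overall

    def test_single_config_space_trains_on_all_rows(self):
        data = toy_data()
        p = Pipeline([PipelineElement("ThresholdClassifier",
                                      fixed_params={"threshold": 0.5})])
        tree, final = run(toy_spec(), p, data)
        assert tree.overall_best_config.assignments == {}
        # final refit saw the full feature width and predicts on all rows
        assert len(final.predict(data.features)) == data.n

    def test_use_test_set_false_reports_no_test_metrics(self):
        data = toy_data()
        tree, _ = run(toy_spec(use_test_set=False), toy_pipeline(), data)
        for fold in tree.outer_folds:
            assert fold.test_metrics == {}
            assert fold.train_metrics == {}


# ---------------------------------------------------------------------------
# Leakage and determinism
# ---------------------------------------------------------------------------


class TestNoLeakage:
    def test_spy_fitted_rows_never_include_validation_or_test(self, spy_log):
        """Every set of rows any element is fitted on is exactly an
        inner-train, outer-train, or full-data index set — never touching
        the corresponding validation/test rows."""
        n = 36
        rng = np.random.default_rng(8)
        X = np.column_stack([np.arange(n), rng.normal(size=n)])  # col 0 = row id
        y = np.array([0, 1] * (n // 2))
        data = DataTriple(X.astype(float), y)
        p = Pipeline([
            PipelineElement("FitSpy"),
            PipelineElement("ThresholdClassifier",
                            hyperparameters={"threshold": [0.0, 1.0]}),
        ])
        tree, _ = run(toy_spec(name="leak"), p, data)

        allowed = {frozenset(range(n))}
        pairs = []  # (train set, forbidden set)
        for fold in tree.outer_folds:
            tr = frozenset(fold.train_indices)
            te = frozenset(fold.test_indices)
            allowed.add(tr)
            pairs.append((tr, te))
            for ev in fold.tested_configs:
                for rec in ev.inner_folds:
                    itr = frozenset(rec.train_indices)
                    ival = frozenset(rec.validation_indices)
                    allowed.add(itr)
                    pairs.append((itr, ival))

        assert spy_log, "spy was never fitted"
        recorded = [frozenset(rows) for _, rows in spy_log]
        for rows in recorded:
            assert rows in allowed
        for train, forbidden in pairs:
            assert not train & forbidden
        # fit count: configs x inner folds + per-fold refit + final refit
        n_cfg_fits = sum(len(ev.inner_folds)
                         for fold in tree.outer_folds
                         for ev in fold.tested_configs)
        assert len(recorded) == n_cfg_fits + len(tree.outer_folds) + 1


class TestDeterminism:
    def test_identical_seeds_identical_result_trees(self):
        data = toy_data()
        t1, _ = run(toy_spec(), toy_pipeline(), data)
        t2, _ = run(toy_spec(), toy_pipeline(), data)
        assert t1.comparable_dict() == t2.comparable_dict()

    def test_random_grid_workflow_deterministic(self):
        data = toy_data()
        spec = toy_spec(optimizer=OptimizerSpec(name="random_grid_search",
                                                n_configurations=4, rng_seed=11))
        t1, _ = run(spec, toy_pipeline(), data)
        t2, _ = run(spec, toy_pipeline(), data)
        assert t1.comparable_dict() == t2.comparable_dict()


# ---------------------------------------------------------------------------
# Constraints at the workflow level
# ---------------------------------------------------------------------------


class TestConstraintSemantics:
    def test_vacuous_constraint_bitwise_identical(self):
        data = toy_data()
        free, _ = run(toy_spec(), toy_pipeline(), data)
        constrained, _ = run(
            toy_spec(constraints=[MinimumPerformanceConstraint(
                "accuracy", -1.0, "mean")]),
            toy_pipeline(), data)
        f = free.comparable_dict()
        c = constrained.comparable_dict()
        f.pop("spec_echo")
        c.pop("spec_echo")
        assert f == c

    @pytest.mark.parametrize("strategy", ["mean", "first", "any"])
    def test_unsatisfiable_constraint_minimal_fold_evaluations(self, strategy):
        data = toy_data()
        tree, _ = run(
            toy_spec(constraints=[MinimumPerformanceConstraint(
                "accuracy", 2.0, strategy)]),
            toy_pipeline(), data)
        for fold in tree.outer_folds:
            for ev in fold.tested_configs:
                assert ev.completed_folds == 1
                assert ev.incomplete

    def test_failed_configs_recorded_and_excluded(self):
        class SometimesBroken:
            def __init__(self, mode="ok"):
                self.mode = mode

            def fit(self, X, y=None):
                if self.mode == "boom":
                    raise ValueError("deliberate failure")
                return self

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        from nestpipe import Capabilities, RegistrationError, register
        try:
            register("SometimesBroken", SometimesBroken,
                     Capabilities(has_predict=True))
        except RegistrationError:
            pass
        data = toy_data()
        p = Pipeline([PipelineElement("SometimesBroken",
                                      hyperparameters={"mode": ["ok", "boom"]})])
        tree, _ = run(toy_spec(), p, data)
        for fold in tree.outer_folds:
            failed = [e for e in fold.tested_configs if e.failed]
            assert len(failed) == 1
            assert "deliberate failure" in failed[0].error
            assert fold.best_config.assignments == {"SometimesBroken__mode": "ok"}

    def test_all_configs_failing_raises(self):
        data = toy_data()
        p = Pipeline([PipelineElement("SometimesBroken",
                                      fixed_params={"mode": "boom"})])
        with pytest.raises(WorkflowError, match="failed"):
            run(toy_spec(), p, data)


# ---------------------------------------------------------------------------
# Per-estimator summary
# ---------------------------------------------------------------------------


def _injected_tree():
    """Two switch children over two outer folds with hand-known metrics."""
    def ev(child, val, bacc):
        cfg = Config({}, frozenset(), {"est": child})
        rec = InnerFoldRecord(0, [0], [1],
                              {"f1_score": val, "balanced_accuracy": bacc},
                              {"f1_score": val, "balanced_accuracy": bacc})
        return ConfigEvaluation(config=cfg, inner_folds=[rec],
                                val_performance=val, completed_folds=1)

    folds = [
        OuterFoldResult(0, [0, 1], [2], tested_configs=[
            ev("A", 0.8, 0.7), ev("A", 0.6, 0.9), ev("B", 0.5, 0.5)]),
        OuterFoldResult(1, [0, 2], [1], tested_configs=[
            ev("A", 0.4, 0.6), ev("B", 0.7, 0.8)]),
    ]
    return ResultTree(name="inj", best_config_metric="f1_score",
                      metrics=["f1_score", "balanced_accuracy"],
                      outer_folds=folds)


class TestPerEstimatorSummary:
    def test_hand_computed_means(self):
        table = get_mean_of_best_validation_configs_per_estimator(_injected_tree())
        # child A: fold 0 best val 0.8 (bacc .7), fold 1 val 0.4 (bacc .6)
        assert table["A"]["f1_score"] == pytest.approx((0.8 + 0.4) / 2)
        assert table["A"]["balanced_accuracy"] == pytest.approx((0.7 + 0.6) / 2)
        # child B present in both folds even though always dominated in fold 0
        assert table["B"]["f1_score"] == pytest.approx((0.5 + 0.7) / 2)

    def test_single_fold_means_equal_fold_values(self):
        tree = _injected_tree()
        tree.outer_folds = tree.outer_folds[:1]
        table = get_mean_of_best_validation_configs_per_estimator(tree)
        assert table["B"]["f1_score"] == pytest.approx(0.5)

    def test_no_switch_raises(self):
        tree = _injected_tree()
        for f in tree.outer_folds:
            for e in f.tested_configs:
                object.__setattr__(e.config, "active_switch_children", {})
        with pytest.raises(WorkflowError, match="switch"):
            get_mean_of_best_validation_configs_per_estimator(tree)

    def test_end_to_end_switch_summary_shape(self):
        data = toy_data()
        sw = Switch("est", [
            PipelineElement("ThresholdClassifier",
                            hyperparameters={"threshold": [0.0, 1.0]}, name="thr"),
            PipelineElement("MajorityClassifier", name="maj"),
        ])
        tree, _ = run(toy_spec(), Pipeline([sw]), data)
        table = get_mean_of_best_validation_configs_per_estimator(tree)
        assert set(table) == {"thr", "maj"}
        for child in table.values():
            assert set(child) == {"accuracy", "balanced_accuracy", "f1_score"}
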