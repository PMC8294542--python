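"""Shared test elements and independent oracles.

The helper elements are deliberately trivial and deterministic so that
every pipeline computation can be checked by hand arithmetic, and the
spy elements expose exactly what data an element was fitted on (for the
leakage checks, the feature matrix carries the absolute row index in
column 0).
"""

from __future__ import annotations

import numpy as np
import pytest

from nestpipe import Capabilities, RegistrationError, register
from nestpipe.composites import Branch, Stack, Switch
from nestpipe.elements import PipelineElement


# ---------------------------------------------------------------------------
# Trivial deterministic elements
# ---------------------------------------------------------------------------


class AddConstant:
    """Transformer: adds a constant to every feature cell."""

    def __init__(self, c=1.0):
        self.c = c

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) + self.c


class SumFeatures:
    """Estimator: predicts the row sum of the features."""

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float).sum(axis=1)


class DoubleInput:
    """Estimator: predicts twice the row sum."""

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        return 2.0 * np.asarray(X, dtype=float).sum(axis=1)


class ScaleBy:
    """Transformer: multiplies features by a factor (a tunable knob)."""

    def __init__(self, factor=1.0):
        self.factor = factor

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) * self.factor


class ThresholdClassifier:
    """Predicts 1 when the row sum exceeds a threshold — deterministic,
    with a tunable hyperparameter for grid tests."""

    def __init__(self, threshold=0.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        return (np.asarray(X, dtype=float).sum(axis=1) > self.threshold).astype(int)

    def predict_proba(self, X):
        pred = self.predict(X)
        out = np.zeros((len(pred), 2))
        out[np.arange(len(pred)), pred] = 1.0
        return out


class FitSpy:
    """Transformer recording the values of feature column 0 at fit time
    (tests put the absolute row index there), then passing data through
    unchanged."""

    log: list = []  # class-level sink, reset by tests

    def __init__(self, tag="spy"):
        self.tag = tag

    def fit(self, X, y=None):
        FitSpy.log.append((self.tag, set(np.asarray(X)[:, 0].astype(int))))
        return self

    def transform(self, X):
        return np.asarray(X)


class CountingScaler:
    """Identity transformer counting its fit calls (cache-hit oracle)."""

    calls: list = []

    def fit(self, X, y=None):
        CountingScaler.calls.append(1)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)


class MinorityDuplicator:
    """Target mutator: duplicates minority rows (in order, cycling) until
    the classes are balanced — deterministic."""

    def fit_resample(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        minority = classes[int(np.argmin(counts))]
        n_new = int(counts.max() - counts.min())
        min_idx = np.flatnonzero(y == minority)
        extra = np.resize(min_idx, n_new) if n_new else np.array([], dtype=int)
        idx = np.concatenate([np.arange(len(y)), extra]).astype(int)
        return X[idx], y[idx], idx


_HELPERS = [
    ("AddConstant", AddConstant, Capabilities(has_transform=True)),
    ("SumFeatures", SumFeatures, Capabilities(has_predict=True)),
    ("DoubleInput", DoubleInput, Capabilities(has_predict=True)),
    ("ScaleBy", ScaleBy, Capabilities(has_transform=True)),
    ("ThresholdClassifier", ThresholdClassifier,
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("FitSpy", FitSpy, Capabilities(has_transform=True)),
    ("CountingScaler", CountingScaler, Capabilities(has_transform=True)),
    ("MinorityDuplicator", MinorityDuplicator, Capabilities(mutates_targets=True)),
]

for kw, ctor, caps in _HELPERS:
    try:
        register(kw, ctor, caps, provenance="user")
    except RegistrationError:
        pass  # already registered by another test module


@pytest.fixture
def spy_log():
    FitSpy.log = []
    yield FitSpy.log
    FitSpy.log = []


# ---------------------------------------------------------------------------
# Independent brute-force space enumerator (oracle)
# ---------------------------------------------------------------------------


def brute_force_count(element) -> int:
    """Count configurations of an element tree by direct recursion,
    independently of the ConfigSpace implementation."""
    if isinstance(element, Switch):
        return sum(brute_force_count(c) for c in element.children)
    if isinstance(element, (Stack, Branch)):
        kids = element.children if isinstance(element, Stack) else element.elements
        n = 1
        for c in kids:
            n *= brute_force_count(c)
        return n
    # leaf; domain expansions are duplicate-free by contract
    n = 1
    for dom in element.hyperparameters.values():
        n *= len(dict.fromkeys(dom.expand()))
    if getattr(element, "test_disabled", False):
        n += 1
    return n


def brute_force_pipeline_count(elements) -> int:
    n = 1
    for e in elements:
        n *= brute_force_count(e)
    return n


def random_small_pipeline(rng: np.random.Generator):
    """A random toy pipeline with optional switch/stack/branch composites
    and test_disabled flags; always ends in a learner."""
    def leaf_transformer(i):
        hp = {}
        if rng.random() < 0.7:
            hp["c"] = list(rng.integers(0, 5, size=rng.integers(1, 4)))
        return PipelineElement("AddConstant", hyperparameters={"c": hp["c"]} if hp else {},
                               test_disabled=bool(rng.random() < 0.4),
                               name=f"t{i}")

    def leaf_learner(i):
        hp = {}
        if rng.random() < 0.7:
            hp["threshold"] = [float(v) for v in rng.normal(size=rng.integers(1, 4))]
        return PipelineElement("ThresholdClassifier", hyperparameters=hp, name=f"l{i}")

    def composite(i, depth):
        kind = rng.integers(3)
        if kind == 0:
            return Switch(f"sw{i}", [middle(f"{i}a", depth + 1),
                                     middle(f"{i}b", depth + 1)])
        if kind == 1:
            return Stack(f"st{i}", [middle(f"{i}a", depth + 1),
                                    middle(f"{i}b", depth + 1)])
        return Branch(f"br{i}", [middle(f"{i}a", depth + 1),
                                 middle(f"{i}b", depth + 1)])

    def middle(i, depth=0):
        if depth < 2 and rng.random() < 0.35:
            return composite(i, depth)
        return leaf_transformer(i)

    n_mid = int(rng.integers(1, 4))
    elements = [middle(str(i)) for i in range(n_mid)]
    elements.append(leaf_learner("end"))
    return elements
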