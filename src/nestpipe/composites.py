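"""Composite pipeline elements: Switch (OR), Stack (AND), Branch (nesting).

* ``Switch`` holds alternative algorithms for one pipeline position;
  exactly one child is active per configuration and the pipeline behaves
  exactly as if that child stood in the switch's place.  Its configuration
  space is the tagged union of the children's (hyperparameter keys are
  namespaced ``switch__child__param`` so union spaces cannot collide).
* ``Stack`` streams the same input to every child and horizontally
  concatenates their outputs: a transformer child contributes its
  transform, an estimator child one prediction column — or its class-
  probability columns when ``use_probabilities`` is set.  Children may not
  change the row count, so target mutators are forbidden inside stacks.
  A stack produces features, never predictions: it must be followed by a
  downstream meta-learner.
* ``Branch`` is a nested sub-pipeline usable wherever a single element
  is; its behaviour is identical to running the inner sequence standalone.

Composites nest freely (a switch of branches inside a stack, etc.).
"""

from __future__ import annotations

import numpy as np

from .elements import Capabilities
from .hyperspace import (
    Config,
    ConfigSpace,
    DefinitionError,
    ProductSpace,
    SEP,
    UnionSpace,
)
from .pipeline import PipelineError, build_runner, _check_rows

__all__ = ["Switch", "Stack", "Branch"]


class _PrefixedSpace(ConfigSpace):
    def __init__(self, prefix: str, inner: ConfigSpace):
        self.prefix = prefix
        self.inner = inner

    def __len__(self):
        return len(self.inner)

    def config_at(self, i: int) -> Config:
        return self.inner.config_at(i).prefixed(self.prefix)


def _check_children(name: str, children) -> list:
    children = list(children)
    names = [c.name for c in children]
    if len(set(names)) != len(names):
        raise DefinitionError(f"composite {name!r} has duplicate child names: {names}")
    return children


# ---------------------------------------------------------------------------
# Switch — OR
# ---------------------------------------------------------------------------


class Switch:
    """OR-element: interchangeable algorithms at one pipeline position."""

    def __init__(self, name: str, children):
        self.name = name
        self.children = _check_children(name, children)
        if len(self.children) < 2:
            raise DefinitionError(f"switch {name!r} needs at least two children")
        self._by_name = {c.name: c for c in self.children}

    def space(self) -> UnionSpace:
        return UnionSpace(self.name, {c.name: c.space() for c in self.children})

    def build_runner(self, config: Config, path: str):
        child_name = config.active_child(path)
        if child_name is None:
            raise DefinitionError(
                f"configuration names no active child for switch {path!r}")
        child = self._by_name.get(child_name)
        if child is None:
            raise DefinitionError(
                f"switch {path!r} has no child named {child_name!r}")
        # inactive children are never constructed, let alone fitted
        return build_runner(child, config, path + SEP + child.name)


# ---------------------------------------------------------------------------
# Stack — AND
# ---------------------------------------------------------------------------


class _StackRunner:
    capabilities = Capabilities(has_transform=True)

    def __init__(self, name: str, child_runners: list, use_probabilities: bool):
        self.name = name
        self.child_runners = child_runners
        self.use_probabilities = use_probabilities
        for r in child_runners:
            if r.capabilities.mutates_targets:
                raise PipelineError(
                    f"stack {name!r}: target mutators are forbidden inside stacks "
                    f"(child {r.name!r})")
            if r.capabilities.is_callback:
                raise DefinitionError(
                    f"stack {name!r}: a callback cannot be a stack child")

    def fit(self, X, y, sc):
        for r in self.child_runners:
            r.fit(X, y, sc)

    def _child_block(self, r, X, y, sc, fit_time: bool) -> np.ndarray:
        caps = r.capabilities
        if caps.has_transform:
            out, _, _ = r.forward(X, y, sc, fit_time)
            return np.asarray(out)
        if self.use_probabilities and caps.has_predict_proba:
            return np.asarray(r.predict_proba(X, sc))
        return np.asarray(r.predict(X, sc)).reshape(-1, 1)

    def forward(self, X, y, sc, fit_time: bool):
        n = np.asarray(X).shape[0]
        blocks = []
        for r in self.child_runners:
            block = self._child_block(r, X, y, sc, fit_time)
            if block.shape[0] != n:
                raise PipelineError(
                    f"stack {self.name!r}: child {r.name!r} changed the row count "
                    f"({n} -> {block.shape[0]})")
            blocks.append(block)
        return np.hstack(blocks), y, sc

    def predict(self, X, sc=None):
        raise PipelineError(
            f"stack {self.name!r} produces concatenated features, not predictions; "
            "add a downstream meta-learner")

    predict_proba = predict


class Stack:
    """AND-element: children share the input; outputs are horizontally
    concatenated in declared order."""

    def __init__(self, name: str, children, use_probabilities: bool = False):
        self.name = name
        self.children = _check_children(name, children)
        if not self.children:
            raise DefinitionError(f"stack {name!r} needs at least one child")
        self.use_probabilities = use_probabilities

    def space(self) -> ConfigSpace:
        return _PrefixedSpace(
            self.name, ProductSpace([c.space() for c in self.children]))

    def build_runner(self, config: Config, path: str):
        runners = []
        for c in self.children:
            child_path = path + SEP + c.name
            if config.is_disabled(child_path):
                continue
            runners.append(build_runner(c, config, child_path))
        if not runners:
            raise PipelineError(f"stack {path!r}: every child is disabled")
        return _StackRunner(path, runners, self.use_probabilities)


# ---------------------------------------------------------------------------
# Branch — nested sub-pipeline
# ---------------------------------------------------------------------------


class _BranchRunner:
    def __init__(self, name: str, elements: list, config: Config, path: str):
        self.name = name
        self.runners = []
        for el in elements:
            child_path = path + SEP + el.name
            if config.is_disabled(child_path):
                continue
            self.runners.append(build_runner(el, config, child_path))
        if not self.runners:
            raise PipelineError(f"branch {path!r}: every inner element is disabled")
        final_caps = self.runners[-1].capabilities
        self.capabilities = Capabilities(
            has_transform=final_caps.has_transform,
            has_predict=final_caps.has_predict,
            has_predict_proba=final_caps.has_predict_proba,
            mutates_targets=any(r.capabilities.mutates_targets for r in self.runners),
        )
        self._fit_output = None

    def fit(self, X, y, sc):
        for r in self.runners[:-1]:
            r.fit(X, y, sc)
            X, y, sc = r.forward(X, y, sc, fit_time=True)
            _check_rows(r.name, X, y, sc)
        final = self.runners[-1]
        final.fit(X, y, sc)
        self._fit_output = final.forward(X, y, sc, fit_time=True)

    def forward(self, X, y, sc, fit_time: bool):
        if fit_time:
            if self._fit_output is None:
                raise PipelineError(f"branch {self.name!r} is not fitted")
            return self._fit_output
        for r in self.runners:
            X, y, sc = r.forward(X, y, sc, fit_time=False)
        return X, y, sc

    def _flow(self, X, sc):
        y = None
        for r in self.runners[:-1]:
            X, y, sc = r.forward(X, y, sc, fit_time=False)
        return X, sc

    def predict(self, X, sc=None):
        X, sc = self._flow(X, sc)
        return self.runners[-1].predict(X, sc)

    def predict_proba(self, X, sc=None):
        X, sc = self._flow(X, sc)
        return self.runners[-1].predict_proba(X, sc)


class Branch:
    """A nested sequence of elements behaving as one element; identical to
    running the inner sequence as a standalone pipeline."""

    def __init__(self, name: str, elements):
        self.name = name
        self.elements = _check_children(name, elements)
        if not self.elements:
            raise DefinitionError(f"branch {name!r} needs at least one inner element")

    def space(self) -> ConfigSpace:
        return _PrefixedSpace(
            self.name, ProductSpace([e.space() for e in self.elements]))

    def build_runner(self, config: Config, path: str):
        return _BranchRunner(self.name, self.elements, config, path)
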