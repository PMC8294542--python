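"""The pipeline engine: data flow through an ordered element sequence.

Semantics of one fit pass, element by element:

* a *disabled* element (per the active configuration) is skipped entirely;
* a transformer is fitted, then hands its transformed features on;
* an estimator anywhere before the end is fitted, then hands its point
  predictions on as a single-column feature matrix (estimator-anywhere);
* a target mutator may resample rows at fit time only — features, targets
  and side-channel rows stay aligned; at predict time it is the identity;
* a callback receives exactly the data the next element will receive; its
  return value is discarded;
* the final element is fitted but produces no successor data.

Predict is pure: transforms are applied, intermediate estimators emit
prediction columns, mutators do nothing, callbacks still fire, and the
final element's predictions are returned, one per input row.

The engine never imputes or otherwise touches values itself; missing
values are legal at entry and must be handled by an element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .elements import Capabilities, CallbackElement, PipelineElement
from .hyperspace import Config, DefinitionError, EMPTY_CONFIG, ProductSpace, SEP

__all__ = [
    "DataTriple",
    "PipelineError",
    "UsageError",
    "CapabilityError",
    "Pipeline",
    "FittedPipeline",
    "attach_callback",
]


class PipelineError(RuntimeError):
    pass


class UsageError(RuntimeError):
    pass


class CapabilityError(RuntimeError):
    pass


@dataclass
class DataTriple:
    """Features, targets, and optional side-channel covariates that travel
    through the pipeline together; row counts always agree."""

    features: np.ndarray
    targets: Optional[np.ndarray] = None
    side_channel: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.features = np.asarray(self.features)
        if self.features.ndim != 2:
            raise DefinitionError("features must be a 2-D matrix")
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise DefinitionError(f"need n >= 1 and p >= 1, got {self.features.shape}")
        if self.targets is not None:
            self.targets = np.asarray(self.targets)
            if self.targets.shape[0] != n:
                raise DefinitionError(
                    f"targets have {self.targets.shape[0]} rows, features have {n}")
        if self.side_channel is not None:
            if len(self.side_channel) != n:
                raise DefinitionError(
                    f"side_channel has {len(self.side_channel)} rows, features have {n}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def subset(self, indices) -> "DataTriple":
        idx = np.asarray(indices)
        return DataTriple(
            self.features[idx],
            None if self.targets is None else self.targets[idx],
            None if self.side_channel is None
            else self.side_channel.iloc[idx].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# Runners: per-configuration, stateful element instances
# ---------------------------------------------------------------------------


class LeafRunner:
    """Adapter driving one constructed algorithm instance."""

    def __init__(self, name: str, instance, capabilities: Capabilities):
        self.name = name
        self.instance = instance
        self.capabilities = capabilities

    def fit(self, X, y, sc):
        caps = self.capabilities
        if caps.is_callback or caps.mutates_targets:
            return  # callbacks fire in forward(); mutators resample in forward()
        self.instance.fit(X, y)

    def forward(self, X, y, sc, fit_time: bool):
        caps = self.capabilities
        if caps.is_callback:
            self.instance(X, y, sc)  # return value deliberately ignored
            return X, y, sc
        if caps.mutates_targets:
            if not fit_time:
                return X, y, sc
            X2, y2, src = self.instance.fit_resample(X, y)
            sc2 = None if sc is None else sc.iloc[np.asarray(src)].reset_index(drop=True)
            return np.asarray(X2), np.asarray(y2), sc2
        if caps.has_transform:
            return np.asarray(self.instance.transform(X)), y, sc
        preds = np.asarray(self.instance.predict(X))
        return preds.reshape(-1, 1), y, sc

    def predict(self, X, sc=None):
        if not self.capabilities.has_predict:
            raise CapabilityError(f"element {self.name!r} has no predict")
        return np.asarray(self.instance.predict(X))

    def predict_proba(self, X, sc=None):
        if not self.capabilities.has_predict_proba:
            raise CapabilityError(f"element {self.name!r} has no predict_proba")
        return np.asarray(self.instance.predict_proba(X))


def build_runner(element, config: Config, path: str):
    """Construct the runner for *element* under *config* (path = flattened
    element position, used to look up this element's parameter keys)."""
    if hasattr(element, "build_runner"):  # composites
        return element.build_runner(config, path)
    if isinstance(element, CallbackElement):
        return LeafRunner(path, element.delegate, element.capabilities)
    if isinstance(element, PipelineElement):
        params = config.params_for(path)
        return LeafRunner(path, element.construct(params), element.capabilities)
    raise DefinitionError(f"{element!r} is not a pipeline element")


def _check_rows(name: str, X, y, sc):
    n = np.asarray(X).shape[0]
    if y is not None and np.asarray(y).shape[0] != n:
        raise PipelineError(
            f"element {name!r} emitted {n} feature rows but {np.asarray(y).shape[0]} targets")
    if sc is not None and len(sc) != n:
        raise PipelineError(
            f"element {name!r} emitted {n} feature rows but {len(sc)} side-channel rows")


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


class Pipeline:
    """An ordered sequence of elements (leaves or composites)."""

    def __init__(self, elements: Sequence):
        elements = list(elements)
        if not elements:
            raise DefinitionError("a pipeline needs at least one element")
        names = [e.name for e in elements]
        if len(set(names)) != len(names):
            raise DefinitionError(f"duplicate element names in pipeline: {names}")
        self.elements = elements

    def space(self) -> ProductSpace:
        """Joint configuration space of the whole pipeline."""
        return ProductSpace([e.space() for e in self.elements])

    # -- fitting -----------------------------------------------------------
    def fit(self, data: DataTriple, config: Config = EMPTY_CONFIG,
            cache=None, cache_ctx: dict | None = None) -> "FittedPipeline":
        X, y, sc = data.features, data.targets, data.side_channel
        enabled = [(i, el) for i, el in enumerate(self.elements)
                   if not config.is_disabled(el.name)]
        if not enabled:
            raise PipelineError("every element of the pipeline is disabled")
        final_idx = enabled[-1][0]
        runners: list = [None] * len(self.elements)
        sig_names: list[str] = []

        for i, el in enumerate(self.elements):
            sig_names.append(el.name)
            if config.is_disabled(el.name):
                continue
            cacheable = (
                cache is not None
                and cache_ctx is not None
                and isinstance(el, PipelineElement)
                and el.capabilities.has_transform
                and not el.capabilities.mutates_targets
            )
            if cacheable:
                from .results_io import transform_cache_key

                key = transform_cache_key(
                    cache_ctx, i, el, _config_signature(config, sig_names))
                hit = cache.get(key)
                if hit is not None:
                    runner, Xt = hit
                    runners[i] = runner
                    if i != final_idx:
                        X, y, sc = Xt, y, sc
                        _check_rows(el.name, X, y, sc)
                    continue
            runner = build_runner(el, config, el.name)
            try:
                runner.fit(X, y, sc)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"element {el.name!r} failed during fit: {exc}") from exc
            runners[i] = runner
            if i == final_idx:
                if cacheable:
                    Xt, _, _ = runner.forward(X, y, sc, fit_time=True)
                    cache.put(key, (runner, Xt))
                continue
            X, y, sc = runner.forward(X, y, sc, fit_time=True)
            _check_rows(el.name, X, y, sc)
            if cacheable:
                cache.put(key, (runner, X))

        return FittedPipeline(
            elements=self.elements,
            runners=runners,
            config=config,
            final_index=final_idx,
            n_features_in=data.features.shape[1],
        )


def _config_signature(config: Config, names: list[str]) -> tuple:
    """Canonical signature of the configuration restricted to the given
    top-level element names (an element plus everything upstream)."""
    names_set = set(names)

    def head(key: str) -> str:
        return key.split(SEP, 1)[0]

    return (
        tuple(sorted((k, repr(v)) for k, v in config.assignments.items()
                     if head(k) in names_set)),
        tuple(sorted(d for d in config.disabled_elements if head(d) in names_set)),
        tuple(sorted((k, v) for k, v in config.active_switch_children.items()
                     if head(k) in names_set)),
    )


@dataclass
class FittedPipeline:
    """Fitted state of a pipeline for one configuration."""

    elements: list
    runners: list
    config: Config
    final_index: int
    n_features_in: int
    feature_names: Optional[list] = None
    target_name: Optional[str] = None

    def _flow(self, X, sc):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise UsageError(
                f"expected a 2-D matrix with {self.n_features_in} columns, "
                f"got shape {X.shape}")
        y = None
        for i, runner in enumerate(self.runners):
            if runner is None or i == self.final_index:
                continue
            X, y, sc = runner.forward(X, y, sc, fit_time=False)
        return X, sc

    def predict(self, X, side_channel=None) -> np.ndarray:
        X, sc = self._flow(X, side_channel)
        return np.asarray(self.runners[self.final_index].predict(X, sc))

    def predict_proba(self, X, side_channel=None) -> np.ndarray:
        final = self.runners[self.final_index]
        if not final.capabilities.has_predict_proba:
            raise CapabilityError(
                f"final element {final.name!r} does not provide predict_proba")
        X, sc = self._flow(X, side_channel)
        return np.asarray(final.predict_proba(X, sc))


def attach_callback(elements: Sequence, position: int, delegate,
                    name: str = "callback") -> list:
    """Insert an inspection callback at *position*; the surrounding data
    flow is bit-identical with and without it."""
    elements = list(elements)
    if not 0 <= position <= len(elements):
        raise DefinitionError(f"position {position} out of range 0..{len(elements)}")
    existing = {e.name for e in elements}
    final = name
    k = 1
    while final in existing:
        final = f"{name}_{k}"
        k += 1
    return elements[:position] + [CallbackElement(final, delegate)] + elements[position:]
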