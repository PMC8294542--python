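"""Parse YAML/JSON workflow definitions into pipelines and specs.

The config document has up to three top-level sections::

    workflow:            # CV schemes, metrics, optimizer, constraints, ...
    elements:            # the pipeline, in order; composites nest
    synthetic:           # optional synthetic-cohort parameters

Element entries are one of::

    {element: Keyword, name: ..., fixed_params: {...},
     hyperparameters: {param: [v1, v2] | {type: float_range, start: , stop: ,
                       step: , range_type: , num_points: } | ...},
     test_disabled: true}
    {switch: name, elements: [...]}
    {stack: name, use_probabilities: bool, elements: [...]}
    {branch: name, elements: [...]}

Errors carry the offending field path so misconfigurations are easy to
locate.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .composites import Branch, Stack, Switch
from .elements import PipelineElement, resolve, RegistrationError
from .hyperspace import (
    BooleanDomain,
    Categorical,
    DefinitionError,
    FloatRange,
    IntegerRange,
)
from .optimization import MinimumPerformanceConstraint, OptimizerSpec
from .synth import SyntheticSpec
from .workflow import CVScheme, WorkflowSpec

__all__ = ["ConfigFileError", "load_config", "parse_domain",
           "parse_elements", "parse_workflow", "parse_synthetic"]


class ConfigFileError(ValueError):
    """A config-document violation, annotated with the field path."""


def _fail(path: str, msg: str):
    raise ConfigFileError(f"{path}: {msg}")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".json",):
            return json.loads(text)
        return yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigFileError(f"{path}: cannot parse document: {exc}") from exc


def parse_domain(spec, where: str):
    if isinstance(spec, (list, tuple)):
        return Categorical(spec)
    if not isinstance(spec, dict):
        _fail(where, f"expected a value list or a domain mapping, got {spec!r}")
    kind = spec.get("type")
    try:
        if kind == "categorical":
            return Categorical(spec["values"])
        if kind == "integer_range":
            return IntegerRange(spec["start"], spec["stop"], spec.get("step", 1))
        if kind == "float_range":
            return FloatRange(
                spec["start"], spec["stop"], spec.get("step"),
                spec.get("range_type", "linspace"), spec.get("num_points", 10))
        if kind == "boolean":
            return BooleanDomain()
    except KeyError as exc:
        _fail(where, f"domain of type {kind!r} is missing field {exc}")
    except DefinitionError as exc:
        _fail(where, str(exc))
    _fail(where, f"unknown domain type {kind!r}")


def _parse_element(entry: dict, where: str):
    if not isinstance(entry, dict):
        _fail(where, f"expected a mapping, got {entry!r}")
    composite_keys = [k for k in ("switch", "stack", "branch") if k in entry]
    if composite_keys:
        kind = composite_keys[0]
        name = entry[kind]
        children = [
            _parse_element(e, f"{where}.elements[{i}]")
            for i, e in enumerate(entry.get("elements", []))
        ]
        try:
            if kind == "switch":
                return Switch(name, children)
            if kind == "stack":
                return Stack(name, children,
                             use_probabilities=bool(entry.get("use_probabilities", False)))
            return Branch(name, children)
        except DefinitionError as exc:
            _fail(where, str(exc))
    if "element" not in entry:
        _fail(where, "entry needs an 'element', 'switch', 'stack' or 'branch' key")
    keyword = entry["element"]
    try:
        resolve(keyword)
    except RegistrationError:
        _fail(f"{where}.element", f"unknown element keyword {keyword!r}")
    hps = {
        p: parse_domain(dspec, f"{where}.hyperparameters.{p}")
        for p, dspec in (entry.get("hyperparameters") or {}).items()
    }
    try:
        return PipelineElement(
            keyword,
            fixed_params=dict(entry.get("fixed_params") or {}),
            hyperparameters=hps,
            test_disabled=bool(entry.get("test_disabled", False)),
            name=entry.get("name"),
        )
    except DefinitionError as exc:
        _fail(where, str(exc))


def parse_elements(doc: dict) -> list:
    entries = doc.get("elements")
    if not entries:
        raise ConfigFileError("elements: the pipeline needs at least one element")
    return [_parse_element(e, f"elements[{i}]") for i, e in enumerate(entries)]


def _parse_cv(spec, where: str) -> CVScheme:
    if not isinstance(spec, dict) or "kind" not in spec:
        _fail(where, "expected a mapping with a 'kind' field")
    try:
        return CVScheme(
            spec["kind"],
            n_splits=spec.get("n_splits", 5),
            test_size=spec.get("test_size", 0.2),
            shuffle=bool(spec.get("shuffle", False)),
            seed=spec.get("seed", 0),
        )
    except DefinitionError as exc:
        _fail(where, str(exc))


def parse_workflow(doc: dict) -> WorkflowSpec:
    wf = doc.get("workflow")
    if not isinstance(wf, dict):
        raise ConfigFileError("workflow: section missing or not a mapping")
    opt = wf.get("optimizer") or {}
    try:
        optimizer = OptimizerSpec(
            name=opt.get("name", "grid_search"),
            n_configurations=opt.get("n_configurations", 10),
            inner_name=opt.get("inner_name", "random_grid_search"),
            rng_seed=opt.get("seed", opt.get("rng_seed", 0)),
        )
    except DefinitionError as exc:
        _fail("workflow.optimizer", str(exc))
    constraints = []
    for i, c in enumerate(wf.get("constraints") or []):
        try:
            constraints.append(MinimumPerformanceConstraint(
                c["metric"], c["threshold"], c.get("strategy", "mean")))
        except (KeyError, DefinitionError) as exc:
            _fail(f"workflow.constraints[{i}]", str(exc))
    try:
        return WorkflowSpec(
            name=wf.get("name", "workflow"),
            outer_cv=_parse_cv(wf.get("outer_cv", {"kind": "k_fold"}),
                               "workflow.outer_cv"),
            inner_cv=_parse_cv(wf.get("inner_cv", {"kind": "k_fold"}),
                               "workflow.inner_cv"),
            metrics=wf.get("metrics", []),
            best_config_metric=wf.get("best_config_metric", ""),
            optimizer=optimizer,
            constraints=constraints,
            use_test_set=bool(wf.get("use_test_set", True)),
            task=wf.get("task", "classification"),
            project_folder=wf.get("project_folder"),
            cache_folder=wf.get("cache_folder"),
            verbosity=int(wf.get("verbosity", 0)),
            stratify=bool(wf.get("stratify", True)),
        )
    except DefinitionError as exc:
        _fail("workflow", str(exc))


def parse_synthetic(doc: dict, seed: int | None = None) -> SyntheticSpec:
    block = dict(doc.get("synthetic") or {})
    if seed is not None:
        block["seed"] = seed
    try:
        return SyntheticSpec(**block)
    except (TypeError, DefinitionError) as exc:
        raise ConfigFileError(f"synthetic: {exc}") from exc
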