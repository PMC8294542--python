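"""Hyperparameter value domains and joint configuration spaces.

A pipeline's tunable surface is described by per-element value domains
(categorical lists, integer/float ranges, booleans).  The joint space of a
pipeline combines element fragments by Cartesian product for sequential
positions and by tagged union for OR-elements (switches).  Every space is
finite and supports positional indexing, so grid enumeration, uniform
sampling, and exact cardinality all derive from one representation.

Key conventions (documented behaviour, not inherited from any toolbox):

* ranges with a ``step`` are half-open ``[start, stop)`` arithmetic
  progressions;
* float ranges without a step expand to ``num_points`` values equally
  spaced on a linear or log10 axis, *including* both endpoints;
* flattened configuration keys join element and parameter names with a
  double underscore, e.g. ``pca__n_components``; nested composites chain
  prefixes (``est__svm__C``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "DefinitionError",
    "ValueDomain",
    "Categorical",
    "IntegerRange",
    "FloatRange",
    "BooleanDomain",
    "as_domain",
    "expand_domain",
    "Config",
    "ConfigSpace",
    "ElementFragment",
    "ProductSpace",
    "UnionSpace",
    "sample_config",
    "SEP",
]

SEP = "__"


class DomainError(ValueError):
    """An ill-formed hyperparameter value domain."""


class DefinitionError(ValueError):
    """An ill-formed element or pipeline definition."""


# ---------------------------------------------------------------------------
# Value domains
# ---------------------------------------------------------------------------


class ValueDomain:
    """Base class for hyperparameter value domains."""

    def expand(self) -> list:
        raise NotImplementedError


@dataclass(frozen=True)
class Categorical(ValueDomain):
    """An explicit, ordered list of candidate values (order is preserved
    as declared; it fixes grid order and downstream tie-breaking)."""

    values: tuple

    def __init__(self, values: Sequence):
        object.__setattr__(self, "values", tuple(values))
        if len(self.values) == 0:
            raise DomainError("categorical domain must contain at least one value")

    def expand(self) -> list:
        return list(self.values)


@dataclass(frozen=True)
class IntegerRange(ValueDomain):
    """Integers in the half-open interval ``[start, stop)`` with ``step``."""

    start: int
    stop: int
    step: int = 1

    def __post_init__(self):
        if self.step <= 0:
            raise DomainError(f"step must be positive, got {self.step}")
        if not self.start < self.stop:
            raise DomainError(f"need start < stop, got [{self.start}, {self.stop})")

    def expand(self) -> list:
        return list(range(self.start, self.stop, self.step))


@dataclass(frozen=True)
class FloatRange(ValueDomain):
    """Real-valued range.

    With ``step``: the arithmetic progression over ``[start, stop)``.
    Without ``step``: ``num_points`` values equally spaced on a linear
    (``range_type='linspace'``) or log10 (``'logspace'``) axis, endpoints
    included.  ``logspace`` requires ``start > 0``.
    """

    start: float
    stop: float
    step: float | None = None
    range_type: str = "linspace"
    num_points: int = 10

    def __post_init__(self):
        if not self.start < self.stop:
            raise DomainError(f"need start < stop, got [{self.start}, {self.stop})")
        if self.step is not None and self.step <= 0:
            raise DomainError(f"step must be positive, got {self.step}")
        if self.range_type not in ("linspace", "logspace"):
            raise DomainError(f"unknown range_type {self.range_type!r}")
        if self.range_type == "logspace" and self.start <= 0:
            raise DomainError("logspace requires start > 0")
        if self.num_points < 1:
            raise DomainError("num_points must be a positive integer")

    def expand(self) -> list:
        if self.step is not None:
            # guard against floating accumulation pushing a point onto stop
            n = int(math.floor((self.stop - self.start - 1e-12) / self.step)) + 1
            return [float(self.start + i * self.step) for i in range(n)]
        if self.range_type == "logspace":
            pts = np.logspace(math.log10(self.start), math.log10(self.stop), self.num_points)
        else:
            pts = np.linspace(self.start, self.stop, self.num_points)
        return [float(v) for v in pts]


@dataclass(frozen=True)
class BooleanDomain(ValueDomain):
    """The two truth values, in ascending order."""

    def expand(self) -> list:
        return [False, True]


def as_domain(obj) -> ValueDomain:
    """Coerce a raw specification (list/tuple or domain) into a ValueDomain."""
    if isinstance(obj, ValueDomain):
        return obj
    if isinstance(obj, (list, tuple)):
        return Categorical(obj)
    raise DomainError(f"cannot interpret {obj!r} as a hyperparameter domain")


def expand_domain(domain: ValueDomain | Sequence) -> list:
    """Expand a domain into its finite, ordered, duplicate-free value list."""
    values = as_domain(domain).expand()
    seen, out = set(), []
    for v in values:
        k = (type(v).__name__, v)
        if k not in seen:
            seen.add(k)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Config:
    """One concrete assignment of values to every tunable of a pipeline.

    ``assignments`` maps flattened keys (``element__param``, chained
    through composites) to concrete values; ``disabled_elements`` names
    elements switched off in this configuration; ``active_switch_children``
    maps each switch path to the name of its active child.
    """

    assignments: Mapping[str, Any] = field(default_factory=dict)
    disabled_elements: frozenset = field(default_factory=frozenset)
    active_switch_children: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "assignments", dict(self.assignments))
        object.__setattr__(self, "disabled_elements", frozenset(self.disabled_elements))
        object.__setattr__(self, "active_switch_children", dict(self.active_switch_children))

    # -- identity ----------------------------------------------------------
    def key(self) -> tuple:
        """Canonical hashable identity (used by optimizers and result logs)."""
        return (
            tuple(sorted(self.assignments.items())),
            tuple(sorted(self.disabled_elements)),
            tuple(sorted(self.active_switch_children.items())),
        )

    def __hash__(self):
        return hash(self.key())

    def __eq__(self, other):
        return isinstance(other, Config) and self.key() == other.key()

    # -- navigation --------------------------------------------------------
    def params_for(self, path: str) -> dict:
        """Parameter assignments belonging directly to the element at *path*."""
        prefix = path + SEP
        out = {}
        for k, v in self.assignments.items():
            if k.startswith(prefix) and SEP not in k[len(prefix):]:
                out[k[len(prefix):]] = v
        return out

    def is_disabled(self, path: str) -> bool:
        return path in self.disabled_elements

    def active_child(self, path: str) -> str | None:
        return self.active_switch_children.get(path)

    # -- composition -------------------------------------------------------
    def prefixed(self, prefix: str) -> "Config":
        p = prefix + SEP
        return Config(
            {p + k: v for k, v in self.assignments.items()},
            frozenset(p + d for d in self.disabled_elements),
            {p + k if k else prefix: v for k, v in self.active_switch_children.items()},
        )

    def merged(self, other: "Config") -> "Config":
        a = dict(self.assignments)
        a.update(other.assignments)
        sw = dict(self.active_switch_children)
        sw.update(other.active_switch_children)
        return Config(a, self.disabled_elements | other.disabled_elements, sw)

    def to_dict(self) -> dict:
        return {
            "assignments": dict(self.assignments),
            "disabled_elements": sorted(self.disabled_elements),
            "active_switch_children": dict(self.active_switch_children),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        return cls(
            d.get("assignments", {}),
            frozenset(d.get("disabled_elements", [])),
            d.get("active_switch_children", {}),
        )


EMPTY_CONFIG = Config()


# ---------------------------------------------------------------------------
# Configuration spaces
# ---------------------------------------------------------------------------


class ConfigSpace:
    """A finite, positionally indexable set of configurations.

    Enumeration order is deterministic: elements in pipeline order, domains
    in declared order, the last domain varying fastest.
    """

    def __len__(self) -> int:
        raise NotImplementedError

    def config_at(self, i: int) -> Config:
        raise NotImplementedError

    def __iter__(self) -> Iterator[Config]:
        for i in range(len(self)):
            yield self.config_at(i)


class ElementFragment(ConfigSpace):
    """Configuration fragment contributed by a single pipeline element:
    the Cartesian product of its expanded domains, plus — when the element
    is marked *test_disabled* — one extra configuration that switches the
    element off entirely (so the optimizer can test whether skipping the
    step helps)."""

    def __init__(self, name: str, domains: Mapping[str, Any] | None = None,
                 test_disabled: bool = False):
        if SEP in name:
            raise DefinitionError(f"element name {name!r} may not contain {SEP!r}")
        self.name = name
        self.param_names: list[str] = []
        self.param_values: list[list] = []
        seen = set()
        for pname, dom in (domains or {}).items():
            if pname in seen:
                raise DefinitionError(f"duplicate hyperparameter {pname!r} on {name!r}")
            seen.add(pname)
            self.param_names.append(pname)
            self.param_values.append(expand_domain(dom))
        self.test_disabled = bool(test_disabled)
        self._enabled_size = 1
        for vals in self.param_values:
            self._enabled_size *= len(vals)

    def __len__(self) -> int:
        return self._enabled_size + (1 if self.test_disabled else 0)

    def config_at(self, i: int) -> Config:
        if not 0 <= i < len(self):
            raise IndexError(i)
        if self.test_disabled and i == self._enabled_size:
            return Config(disabled_elements=frozenset({self.name}))
        assignments = {}
        # mixed-radix decode, last domain fastest-varying
        rem = i
        for pname, vals in zip(reversed(self.param_names), reversed(self.param_values)):
            rem, j = divmod(rem, len(vals))
            assignments[f"{self.name}{SEP}{pname}"] = vals[j]
        return Config(assignments)


class ProductSpace(ConfigSpace):
    """Cartesian product of sub-spaces (sequential pipeline positions,
    stack/branch children).  Cardinality is the product of the parts'."""

    def __init__(self, parts: Sequence[ConfigSpace]):
        self.parts = list(parts)
        if not self.parts:
            raise DefinitionError("empty pipeline has no configuration space")

    def __len__(self) -> int:
        n = 1
        for p in self.parts:
            n *= len(p)
        return n

    def config_at(self, i: int) -> Config:
        if not 0 <= i < len(self):
            raise IndexError(i)
        rem = i
        picks: list[Config] = []
        for part in reversed(self.parts):
            rem, j = divmod(rem, len(part))
            picks.append(part.config_at(j))
        cfg = EMPTY_CONFIG
        for c in reversed(picks):
            cfg = cfg.merged(c)
        return cfg


class UnionSpace(ConfigSpace):
    """Tagged union over the children of a switch (OR-element): exactly one
    child is active per configuration and only that child contributes
    parameter keys.  Cardinality is the *sum* of the children's."""

    def __init__(self, name: str, children: Mapping[str, ConfigSpace]):
        if SEP in name:
            raise DefinitionError(f"switch name {name!r} may not contain {SEP!r}")
        if len(children) < 2:
            raise DefinitionError(f"switch {name!r} needs at least two children")
        self.name = name
        self.child_names = list(children)
        self.children = dict(children)

    def __len__(self) -> int:
        return sum(len(c) for c in self.children.values())

    def child_space(self, child_name: str) -> ConfigSpace:
        """The slice of this union belonging to one child, as a standalone
        space whose configs carry the switch tag (used by the per-child
        switch optimizer)."""
        return _TaggedChildSpace(self, child_name)

    def config_at(self, i: int) -> Config:
        if not 0 <= i < len(self):
            raise IndexError(i)
        for cname in self.child_names:
            child = self.children[cname]
            if i < len(child):
                return self._tag(cname, child.config_at(i))
            i -= len(child)
        raise AssertionError("unreachable")

    def _tag(self, child_name: str, child_cfg: Config) -> Config:
        tagged = child_cfg.prefixed(self.name)
        return Config(
            tagged.assignments,
            tagged.disabled_elements,
            {**tagged.active_switch_children, self.name: child_name},
        )


class _TaggedChildSpace(ConfigSpace):
    def __init__(self, union: UnionSpace, child_name: str):
        if child_name not in union.children:
            raise DefinitionError(f"switch {union.name!r} has no child {child_name!r}")
        self.union = union
        self.child_name = child_name

    def __len__(self) -> int:
        return len(self.union.children[self.child_name])

    def config_at(self, i: int) -> Config:
        return self.union._tag(self.child_name, self.union.children[self.child_name].config_at(i))


def sample_config(space: ConfigSpace, rng_seed: int | np.random.Generator) -> Config:
    """Draw one configuration uniformly from the enumerated space."""
    if len(space) == 0:
        raise DefinitionError("cannot sample from an empty configuration space")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return space.config_at(int(rng.integers(len(space))))
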