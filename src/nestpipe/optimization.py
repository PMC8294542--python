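"""Hyperparameter optimization strategies behind an ask/tell interface.

An optimizer is initialized with a configuration space, streams candidate
configurations through ``ask()``, and receives one ``tell(config,
performance)`` per asked configuration.  Grid and random-grid search are
stateless (they ignore tells), but the contract is preserved so adaptive
external optimizers can plug in through ``register_optimizer``.

The *switch* meta-optimizer addresses pipelines whose final position is an
OR-element of learning algorithms: it optimizes each child in its own
individual hyperparameter space, spending up to ``n_configurations``
evaluations per child (sub-optimizer: random grid search by default).

``MinimumPerformanceConstraint`` aborts the remaining inner folds of a
configuration whose running performance is on the wrong side of a
threshold (strategies: mean of completed folds / first fold only / any
fold), so unpromising candidates are dismissed early.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .hyperspace import Config, ConfigSpace, DefinitionError, ProductSpace, UnionSpace
from .metrics import Direction, METRIC_NAMES, direction as metric_direction

__all__ = [
    "OptimizerSpec",
    "MinimumPerformanceConstraint",
    "Optimizer",
    "GridSearch",
    "RandomGridSearch",
    "SwitchOptimizer",
    "register_optimizer",
    "make_optimizer",
    "should_continue",
]


@dataclass
class OptimizerSpec:
    """Declarative optimizer choice for a workflow."""

    name: str = "grid_search"
    n_configurations: int = 10
    inner_name: str = "random_grid_search"  # sub-optimizer of the switch strategy
    rng_seed: int = 0

    def __post_init__(self):
        if self.name not in OPTIMIZERS:
            raise DefinitionError(
                f"unknown optimizer {self.name!r}; registered: {sorted(OPTIMIZERS)}")
        if self.n_configurations < 1:
            raise DefinitionError("n_configurations must be a positive integer")


@dataclass(frozen=True)
class MinimumPerformanceConstraint:
    """Lower (or, for error metrics, upper) performance bound a
    configuration must meet for its remaining folds to be evaluated."""

    metric_name: str
    threshold: float
    strategy: str = "mean"

    def __post_init__(self):
        if self.metric_name not in METRIC_NAMES:
            raise DefinitionError(f"unknown constraint metric {self.metric_name!r}")
        if self.strategy not in ("first", "any", "mean"):
            raise DefinitionError(
                f"unknown constraint strategy {self.strategy!r}; "
                "expected first, any, or mean")


def should_continue(partial_fold_performances: Sequence[float],
                    constraint: Optional[MinimumPerformanceConstraint],
                    direction: Direction | None = None) -> bool:
    """Decide whether to evaluate the next inner fold given the constraint
    metric's values on the folds completed so far."""
    if constraint is None:
        return True
    vals = [float(v) for v in partial_fold_performances]
    if not vals:
        return True
    if direction is None:
        direction = metric_direction(constraint.metric_name)
    if direction is Direction.GREATER_IS_BETTER:
        ok = lambda v: v >= constraint.threshold  # noqa: E731
    else:
        ok = lambda v: v <= constraint.threshold  # noqa: E731
    if constraint.strategy == "mean":
        return ok(float(np.mean(vals)))
    if constraint.strategy == "first":
        return ok(vals[0])
    return all(ok(v) for v in vals)  # "any" fold violating aborts


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class Optimizer:
    """Base ask/tell optimizer; subclasses implement ``_stream``."""

    def __init__(self, space: ConfigSpace, spec: OptimizerSpec):
        if len(space) == 0:
            raise DefinitionError("cannot optimize over an empty configuration space")
        self.space = space
        self.spec = spec
        self._asked: set = set()
        self._pending: set = set()
        self.history: list[tuple[Config, float]] = []

    def ask(self) -> Iterator[Config]:
        for cfg in self._stream():
            self._asked.add(cfg.key())
            self._pending.add(cfg.key())
            yield cfg

    def tell(self, config: Config, performance: float) -> None:
        if config.key() not in self._asked:
            raise DefinitionError("tell() received a configuration that was never asked")
        self._pending.discard(config.key())
        self.history.append((config, float(performance)))

    @property
    def complete(self) -> bool:
        return not self._pending and len(self._asked) > 0

    def _stream(self) -> Iterator[Config]:
        raise NotImplementedError


class GridSearch(Optimizer):
    """Exhaustive enumeration of the space in deterministic order."""

    def _stream(self) -> Iterator[Config]:
        yield from self.space


class RandomGridSearch(Optimizer):
    """A seed-deterministic sample of ``min(n_configurations, |space|)``
    distinct grid points."""

    def _stream(self) -> Iterator[Config]:
        size = len(self.space)
        n = min(self.spec.n_configurations, size)
        rng = np.random.default_rng(self.spec.rng_seed)
        for i in rng.choice(size, size=n, replace=False):
            yield self.space.config_at(int(i))


class SwitchOptimizer(Optimizer):
    """Per-child optimization for pipelines ending in a Switch: each child
    of the final OR-element gets its own sub-optimizer over its individual
    space, capped at ``n_configurations`` evaluations per child."""

    def _child_spaces(self) -> list[ConfigSpace]:
        space = self.space
        if isinstance(space, ProductSpace) and isinstance(space.parts[-1], UnionSpace):
            union = space.parts[-1]
            return [
                ProductSpace(space.parts[:-1] + [union.child_space(c)])
                for c in union.child_names
            ]
        if isinstance(space, UnionSpace):
            return [space.child_space(c) for c in space.child_names]
        raise DefinitionError(
            "the switch optimizer requires the pipeline's final position to be "
            "a Switch element")

    def _stream(self) -> Iterator[Config]:
        inner_cls = OPTIMIZERS[self.spec.inner_name]
        for k, child_space in enumerate(self._child_spaces()):
            sub_spec = OptimizerSpec(
                name=self.spec.inner_name,
                n_configurations=self.spec.n_configurations,
                rng_seed=(self.spec.rng_seed + 7919 * (k + 1)) % (2**31),
            )
            sub = inner_cls(child_space, sub_spec)
            for i, cfg in enumerate(sub.ask()):
                if i >= self.spec.n_configurations:
                    break
                yield cfg


OPTIMIZERS: dict[str, type] = {
    "grid_search": GridSearch,
    "random_grid_search": RandomGridSearch,
    "switch": SwitchOptimizer,
}


def register_optimizer(name: str, cls: type) -> None:
    """Plug-in hook for external ask/tell optimizers."""
    if name in OPTIMIZERS:
        raise DefinitionError(f"optimizer name {name!r} already registered")
    if not issubclass(cls, Optimizer):
        raise DefinitionError("an optimizer must subclass Optimizer")
    OPTIMIZERS[name] = cls


def make_optimizer(spec: OptimizerSpec, space: ConfigSpace) -> Optimizer:
    return OPTIMIZERS[spec.name](space, spec)
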