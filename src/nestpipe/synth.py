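"""Seeded synthetic tabular data emulating a small clinical prediction
cohort: ~300 patients, a dozen numeric/binary features, a binary outcome
with roughly one third positives.

The generator produces class-shifted Gaussian informative features (the
standardized mean shift is ``effect_size``), a binary "comorbidity-like"
feature whose prevalence differs by class, pure-noise filler features,
and optional missingness injected completely at random.  A ground-truth
descriptor records which columns carry signal.  Everything is
deterministic under the seed.

What this emulates — and what it does not: real clinical tables have
correlated features, non-Gaussian marginals and informative missingness;
here features are independent given the class and missingness is MCAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hyperspace import DefinitionError
from .pipeline import DataTriple

__all__ = ["SyntheticSpec", "generate", "to_dataframe"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the demonstration conditions: 299 samples, 12
    predictors, ~32% positive class.  ``effect_size`` is the standardized
    mean shift of the informative features between classes (1.0 by
    default — a clearly learnable but not trivial signal).
    """

    n_samples: int = 299
    n_features: int = 12
    positive_rate: float = 0.32
    effect_size: float = 1.0
    n_informative: int = 4
    missing_rate: float = 0.0
    task: str = "classification"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.positive_rate < 1:
            raise DefinitionError("positive_rate must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise DefinitionError("missing_rate must lie in [0, 1)")
        if self.n_informative > self.n_features:
            raise DefinitionError("n_informative cannot exceed n_features")
        if self.task not in ("classification", "regression"):
            raise DefinitionError(f"unknown task {self.task!r}")


def generate(spec: SyntheticSpec) -> tuple[DataTriple, dict]:
    """Draw one synthetic cohort; returns the data and a ground-truth
    descriptor (informative columns, comorbidity column, effect size)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    if spec.task == "classification":
        y = (rng.random(n) < spec.positive_rate).astype(int)
    else:
        y = rng.normal(size=n)

    X = rng.normal(size=(n, p))
    informative = []
    comorbidity = None
    k = spec.n_informative
    if spec.effect_size != 0 and k > 0:
        if spec.task == "classification":
            shift_target = y.astype(float)
        else:
            shift_target = (y - y.mean()) / (y.std() or 1.0)
        n_gauss = k if spec.task == "regression" else max(k - 1, 0)
        for j in range(n_gauss):
            X[:, j] += spec.effect_size * shift_target
            informative.append(j)
        if spec.task == "classification" and k >= 1:
            # binary comorbidity-like column: prevalence differs by class
            j = n_gauss
            hi, lo = 0.7, 0.3
            prob = np.where(y == 1, hi, lo)
            X[:, j] = (rng.random(n) < prob).astype(float)
            comorbidity = j
            informative.append(j)

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        X[mask] = np.nan

    side = pd.DataFrame({"sample_id": np.arange(n)})
    descriptor = {
        "informative": informative,
        "comorbidity": comorbidity,
        "effect_size": spec.effect_size,
        "positive_rate": spec.positive_rate,
        "seed": spec.seed,
    }
    return DataTriple(X, y, side), descriptor


def to_dataframe(data: DataTriple, target_name: str = "target") -> pd.DataFrame:
    """Features + target as one table (feature columns f0..f{p-1})."""
    p = data.features.shape[1]
    df = pd.DataFrame(data.features, columns=[f"f{j}" for j in range(p)])
    if data.targets is not None:
        df[target_name] = data.targets
    return df
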