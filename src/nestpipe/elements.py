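"""Element registry, the adapter contract, and built-in elements.

Algorithms enter a pipeline through a keyword registry: a keyword maps to
a constructor plus a declaration of capabilities (transform / predict /
predict_proba / target mutation / callback).  Registration runs a small
conformance probe so misdeclared capabilities fail loudly up front.

Built-ins fall in three groups:

* dependency-free reference learners and transformers (constant/majority/
  nearest-centroid classifiers, mean regressor, standardizing scaler, mean
  imputer) — deterministic, fast, and sufficient to exercise the whole
  framework without heavyweight models;
* the bespoke elements: ``LassoFeatureSelection`` (rank features by the
  absolute coefficients of an L1-penalized linear fit, keep the top
  percentile) and ``ImbalancedDataTransformer`` (random under-/over-
  sampling and SMOTE as fit-time target mutators);
* host-environment entries resolving scikit-learn classes lazily by
  keyword ('StandardScaler', 'PCA', 'RandomForestClassifier', ...).
"""

from __future__ import annotations

import importlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .hyperspace import DefinitionError, ElementFragment, ValueDomain, as_domain

__all__ = [
    "Capabilities",
    "RegistryEntry",
    "RegistrationError",
    "register",
    "resolve",
    "registered_keywords",
    "registry_table",
    "PipelineElement",
    "CallbackElement",
    "ConstantClassifier",
    "MajorityClassifier",
    "NearestCentroidClassifier",
    "MeanRegressor",
    "ReferenceScaler",
    "MeanImputer",
    "LassoFeatureSelection",
    "ImbalancedDataTransformer",
]


@dataclass(frozen=True)
class Capabilities:
    has_transform: bool = False
    has_predict: bool = False
    has_predict_proba: bool = False
    mutates_targets: bool = False
    is_callback: bool = False

    def __post_init__(self):
        if not (self.has_transform or self.has_predict
                or self.mutates_targets or self.is_callback):
            raise DefinitionError(
                "an element must transform, predict, mutate targets, or be a callback")


class RegistrationError(ValueError):
    pass


@dataclass
class RegistryEntry:
    keyword: str
    constructor: object          # callable, or "module:Class" string for lazy host entries
    capabilities: Capabilities
    provenance: str = "user"     # builtin | host-environment | user

    def construct(self, **params):
        ctor = self.constructor
        if isinstance(ctor, str):
            module, clsname = ctor.split(":")
            ctor = getattr(importlib.import_module(module), clsname)
        return ctor(**params)


_REGISTRY: dict[str, RegistryEntry] = {}


def _probe(entry: RegistryEntry) -> None:
    """Fit/transform/predict smoke test on a 4x2 toy problem."""
    caps = entry.capabilities
    if caps.is_callback:
        return
    X = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1, 0, 1])
    try:
        obj = entry.construct()
    except Exception as exc:  # noqa: BLE001
        raise RegistrationError(f"{entry.keyword!r}: constructor failed: {exc}") from exc
    if caps.mutates_targets:
        if not hasattr(obj, "fit_resample"):
            raise RegistrationError(f"{entry.keyword!r}: mutates_targets but no fit_resample")
        return
    if not hasattr(obj, "fit"):
        raise RegistrationError(f"{entry.keyword!r}: element lacks fit")
    try:
        obj.fit(X, y)
    except Exception as exc:  # noqa: BLE001
        raise RegistrationError(f"{entry.keyword!r}: fit probe failed: {exc}") from exc
    for cap, meth in (("has_transform", "transform"), ("has_predict", "predict"),
                      ("has_predict_proba", "predict_proba")):
        if getattr(caps, cap):
            if not hasattr(obj, meth):
                raise RegistrationError(f"{entry.keyword!r}: declared {cap} but lacks {meth}")
            try:
                getattr(obj, meth)(X)
            except Exception as exc:  # noqa: BLE001
                raise RegistrationError(
                    f"{entry.keyword!r}: {meth} probe failed: {exc}") from exc


def register(keyword: str, constructor, capabilities: Capabilities,
             provenance: str = "user", probe: bool = True) -> RegistryEntry:
    """Register a constructor under a (case-sensitive, unique) keyword."""
    if keyword in _REGISTRY:
        raise RegistrationError(f"keyword {keyword!r} already registered")
    entry = RegistryEntry(keyword, constructor, capabilities, provenance)
    if probe and provenance != "host-environment":
        _probe(entry)
    _REGISTRY[keyword] = entry
    return entry


def resolve(keyword: str) -> RegistryEntry:
    try:
        return _REGISTRY[keyword]
    except KeyError:
        raise RegistrationError(f"unknown element keyword {keyword!r}") from None


def registered_keywords() -> list[str]:
    return list(_REGISTRY)


def registry_table() -> list[dict]:
    """JSON-ready export of the registry (keyword, capabilities, provenance)."""
    return [
        {
            "keyword": e.keyword,
            "capabilities": {
                "has_transform": e.capabilities.has_transform,
                "has_predict": e.capabilities.has_predict,
                "has_predict_proba": e.capabilities.has_predict_proba,
                "mutates_targets": e.capabilities.mutates_targets,
                "is_callback": e.capabilities.is_callback,
            },
            "provenance": e.provenance,
        }
        for e in _REGISTRY.values()
    ]


# ---------------------------------------------------------------------------
# Element specifications
# ---------------------------------------------------------------------------


@dataclass
class PipelineElement:
    """One pipeline step: a registry keyword plus fixed parameters,
    hyperparameter domains, and the *test_disabled* flag that adds an
    explicit on/off switch to the element's configuration space."""

    keyword: str
    fixed_params: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    test_disabled: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.name is None:
            self.name = self.keyword
        overlap = set(self.fixed_params) & set(self.hyperparameters)
        if overlap:
            raise DefinitionError(
                f"{self.name!r}: parameters {sorted(overlap)} are both fixed and tuned")
        self.hyperparameters = {k: as_domain(v) for k, v in self.hyperparameters.items()}
        self.entry = resolve(self.keyword)

    @property
    def capabilities(self) -> Capabilities:
        return self.entry.capabilities

    def space(self) -> ElementFragment:
        return ElementFragment(self.name, self.hyperparameters, self.test_disabled)

    def construct(self, config_params: dict):
        unknown = set(config_params) - set(self.hyperparameters)
        if unknown:
            raise DefinitionError(f"{self.name!r}: unexpected parameters {sorted(unknown)}")
        return self.entry.construct(**{**self.fixed_params, **config_params})


@dataclass
class CallbackElement:
    """Inspection hook: the delegate is invoked with exactly the data the
    next element will receive; its return value is ignored."""

    name: str
    delegate: object  # callable(X, y, side_channel)

    @property
    def capabilities(self) -> Capabilities:
        return Capabilities(is_callback=True)

    def space(self) -> ElementFragment:
        return ElementFragment(self.name)

    def construct(self, config_params: dict):
        return self.delegate


# ---------------------------------------------------------------------------
# Reference learners / transformers (dependency-free, deterministic)
# ---------------------------------------------------------------------------


class ConstantClassifier:
    """Always predicts a fixed label."""

    def __init__(self, constant=0):
        self.constant = constant

    def fit(self, X, y):
        self.classes_ = np.unique(np.concatenate([np.asarray(y), [self.constant]]))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.constant)

    def predict_proba(self, X):
        proba = np.zeros((np.asarray(X).shape[0], len(self.classes_)))
        proba[:, int(np.searchsorted(self.classes_, self.constant))] = 1.0
        return proba


class MajorityClassifier:
    """Predicts the most frequent training label (ties: smallest label);
    class probabilities are the training frequencies."""

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.majority_ = self.classes_[int(np.argmax(counts))]
        self.freq_ = counts / counts.sum()
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.majority_)

    def predict_proba(self, X):
        return np.tile(self.freq_, (np.asarray(X).shape[0], 1))


class NearestCentroidClassifier:
    """Predicts the class whose training centroid is nearest in Euclidean
    distance (ties: smaller class label)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def _dist(self, X):
        X = np.asarray(X, dtype=float)
        return np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)

    def predict(self, X):
        return self.classes_[np.argmin(self._dist(X), axis=1)]

    def predict_proba(self, X):
        pred = np.argmin(self._dist(X), axis=1)
        proba = np.zeros((len(pred), len(self.classes_)))
        proba[np.arange(len(pred)), pred] = 1.0
        return proba


class MeanRegressor:
    """Predicts the training-target mean."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(np.asarray(y, dtype=float)))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class ReferenceScaler:
    """Standardizes columns to zero mean / unit variance using training
    statistics (constant columns keep scale 1)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


class MeanImputer:
    """Replaces missing cells with the training column mean (all-missing
    columns impute 0)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(X, axis=0)
        self.fill_ = np.where(np.isnan(m), 0.0, m)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        idx = np.where(np.isnan(X))
        X[idx] = self.fill_[idx[1]]
        return X


# ---------------------------------------------------------------------------
# Bespoke elements
# ---------------------------------------------------------------------------


class LassoFeatureSelection:
    """Feature selection by L1-penalized linear regression coefficients.

    Fits a Lasso with penalty weight ``alpha`` on internally standardized
    inputs, ranks features by absolute coefficient (descending), and keeps
    the top ``ceil(percentile * p)`` features.  ``transform`` selects the
    stored columns in original order — no refit at transform time.

    Parameters
    ----------
    alpha : float, > 0
        L1 penalty weight.
    percentile : float in (0, 1]
        Fraction of features to keep.
    """

    def __init__(self, alpha: float = 1.0, percentile: float = 0.5):
        if not 0 < percentile <= 1:
            raise DefinitionError(f"percentile must be in (0, 1], got {percentile}")
        if alpha <= 0:
            raise DefinitionError(f"alpha must be positive, got {alpha}")
        self.alpha = alpha
        self.percentile = percentile

    def fit(self, X, y):
        from sklearn.linear_model import Lasso

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        model = Lasso(alpha=self.alpha, tol=1e-6, max_iter=10_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit((X - mu) / sd, y)
        coef = np.abs(model.coef_)
        k = int(np.ceil(self.percentile * p))
        if np.all(coef == 0):
            warnings.warn(
                "all Lasso coefficients are zero; keeping the first "
                f"{k} feature columns", stacklevel=2)
            keep = np.arange(k)
        else:
            order = np.argsort(-coef, kind="stable")  # ties: earlier column first
            keep = np.sort(order[:k])
        self.mask_ = keep
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.mask_]


class ImbalancedDataTransformer:
    """Class-rebalancing target mutator (fit-time only).

    ``RandomUnderSampler`` drops majority rows uniformly at random until
    class counts are equal; ``RandomOverSampler`` duplicates minority rows
    uniformly until equal; ``SMOTE`` adds synthetic minority samples drawn
    uniformly on segments between a random minority row and one of its
    k=5 nearest minority neighbours (Euclidean) until equal.  Row order is
    original rows in original order followed by synthesized rows, for
    reproducibility.  At predict time the element is the identity.
    """

    METHODS = ("RandomUnderSampler", "RandomOverSampler", "SMOTE")
    K_NEIGHBORS = 5

    def __init__(self, method_name: str = "RandomUnderSampler", random_state: int = 0):
        if method_name not in self.METHODS:
            raise DefinitionError(
                f"unknown resampling method {method_name!r}; expected one of {self.METHODS}")
        self.method_name = method_name
        self.random_state = random_state

    def fit_resample(self, X, y):
        """Returns (X_res, y_res, source_indices); source_indices maps each
        output row to the input row it derives from (synthetic SMOTE rows
        map to their base minority row), so side-channel data can follow."""
        X = np.asarray(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise DefinitionError(
                f"resampling requires binary targets, got {len(classes)} classes")
        rng = np.random.default_rng(self.random_state)
        minority = classes[int(np.argmin(counts))]
        majority = classes[int(np.argmax(counts))]
        if counts[0] == counts[1]:
            idx = np.arange(len(y))
            return X, y, idx
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y == majority)

        if self.method_name == "RandomUnderSampler":
            keep_maj = np.sort(rng.choice(maj_idx, size=len(min_idx), replace=False))
            keep = np.sort(np.concatenate([keep_maj, min_idx]))
            return X[keep], y[keep], keep

        n_new = len(maj_idx) - len(min_idx)
        if self.method_name == "RandomOverSampler":
            extra = rng.choice(min_idx, size=n_new, replace=True)
        else:  # SMOTE
            if len(min_idx) < 2:
                warnings.warn(
                    "SMOTE needs at least 2 minority samples; falling back to "
                    "duplication", stacklevel=2)
                extra = rng.choice(min_idx, size=n_new, replace=True)
            else:
                return self._smote(X, y, min_idx, n_new, rng)
        idx = np.concatenate([np.arange(len(y)), extra])
        return X[idx], y[idx], idx

    def _smote(self, X, y, min_idx, n_new, rng):
        Xm = np.asarray(X, dtype=float)[min_idx]
        # pairwise distances among minority rows
        d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        k = min(self.K_NEIGHBORS, len(min_idx) - 1)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        base = rng.integers(len(min_idx), size=n_new)
        neigh = nn[base, rng.integers(k, size=n_new)]
        lam = rng.uniform(size=n_new)[:, None]
        synth = Xm[base] + lam * (Xm[neigh] - Xm[base])
        X_out = np.vstack([np.asarray(X, dtype=float), synth])
        y_out = np.concatenate([y, np.full(n_new, y[min_idx[0]])])
        src = np.concatenate([np.arange(len(y)), min_idx[base]])
        return X_out, y_out, src


# ---------------------------------------------------------------------------
# Default registry contents
# ---------------------------------------------------------------------------

_BUILTINS = [
    ("ConstantClassifier", ConstantClassifier,
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("MajorityClassifier", MajorityClassifier,
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("NearestCentroidClassifier", NearestCentroidClassifier,
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("MeanRegressor", MeanRegressor, Capabilities(has_predict=True)),
    ("ReferenceScaler", ReferenceScaler, Capabilities(has_transform=True)),
    ("MeanImputer", MeanImputer, Capabilities(has_transform=True)),
    ("LassoFeatureSelection", LassoFeatureSelection, Capabilities(has_transform=True)),
    ("ImbalancedDataTransformer", ImbalancedDataTransformer,
     Capabilities(mutates_targets=True)),
]

_HOST = [
    ("StandardScaler", "sklearn.preprocessing:StandardScaler",
     Capabilities(has_transform=True)),
    ("SimpleImputer", "sklearn.impute:SimpleImputer", Capabilities(has_transform=True)),
    ("PCA", "sklearn.decomposition:PCA", Capabilities(has_transform=True)),
    ("RandomForestClassifier", "sklearn.ensemble:RandomForestClassifier",
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("GradientBoostingClassifier", "sklearn.ensemble:GradientBoostingClassifier",
     Capabilities(has_predict=True, has_predict_proba=True)),
    ("SVC", "sklearn.svm:SVC", Capabilities(has_predict=True)),
    ("LinearSVC", "sklearn.svm:LinearSVC", Capabilities(has_predict=True)),
    ("DecisionTreeClassifier", "sklearn.tree:DecisionTreeClassifier",
     Capabilities(has_predict=True, has_predict_proba=True)),
]


def _install_defaults():
    for kw, ctor, caps in _BUILTINS:
        if kw not in _REGISTRY:
            register(kw, ctor, caps, provenance="builtin", probe=False)
    for kw, path, caps in _HOST:
        if kw not in _REGISTRY:
            register(kw, path, caps, provenance="host-environment", probe=False)


_install_defaults()
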