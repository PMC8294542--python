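"""Result logging, single-file model persistence, and transform caching.

Three concerns live here:

* the **result tree** — a nested, JSON-serializable record of the whole
  run: per outer fold the dummy baseline, every tested configuration with
  its per-inner-fold train/validation metrics, the fold's best
  configuration and (optionally) test metrics, and the overall winner;
* the **model archive** — a fitted pipeline persisted as one
  ``.photon`` file (a zip holding a JSON manifest, the pickled fitted
  state, and a SHA-256 integrity checksum); loading it in a fresh process
  reproduces predictions bitwise;
* the **transform cache** — content-addressed storage of fitted
  transformers and their outputs, keyed over the dataset fingerprint, the
  fold's training indices, the element's position/keyword/fixed params,
  and the configuration of the element and everything upstream, so that
  partially overlapping configurations recompute shared prefixes only
  once.  Cached and cache-free runs are bitwise identical.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .elements import CallbackElement, PipelineElement, resolve, RegistrationError
from .hyperspace import Config

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "ArchiveError",
    "InnerFoldRecord",
    "ConfigEvaluation",
    "OuterFoldResult",
    "ResultTree",
    "write_results",
    "read_results",
    "save_model",
    "load_model",
    "Cache",
    "transform_cache_key",
    "dataset_fingerprint",
]

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    pass


class ArchiveError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Result tree
# ---------------------------------------------------------------------------


def _metric_dict(d: dict) -> dict:
    return {k: (None if v is None else float(v)) for k, v in d.items()}


@dataclass
class InnerFoldRecord:
    fold_id: int
    train_indices: list
    validation_indices: list
    train_metrics: dict
    validation_metrics: dict

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "train_indices": [int(i) for i in self.train_indices],
            "validation_indices": [int(i) for i in self.validation_indices],
            "train_metrics": _metric_dict(self.train_metrics),
            "validation_metrics": _metric_dict(self.validation_metrics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InnerFoldRecord":
        return cls(d["fold_id"], d["train_indices"], d["validation_indices"],
                   d["train_metrics"], d["validation_metrics"])


@dataclass
class ConfigEvaluation:
    """One tested hyperparameter configuration and its inner-fold record.

    ``val_performance`` is the arithmetic mean of the best-config metric
    over the *completed* inner folds; a configuration aborted by a
    performance constraint is flagged ``incomplete`` and one whose fit
    raised is flagged ``failed`` — both are excluded from best-config
    selection whenever a complete competitor exists."""

    config: Config
    inner_folds: list = field(default_factory=list)
    val_performance: Optional[float] = None
    completed_folds: int = 0
    incomplete: bool = False
    failed: bool = False
    error: Optional[str] = None
    computation_time: float = 0.0

    def mean_validation_metrics(self) -> dict:
        """Mean of each metric over completed inner folds' validation splits."""
        out: dict = {}
        if not self.inner_folds:
            return out
        for m in self.inner_folds[0].validation_metrics:
            vals = [f.validation_metrics[m] for f in self.inner_folds
                    if f.validation_metrics.get(m) is not None]
            if vals:
                out[m] = float(np.mean(vals))
        return out

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "inner_folds": [f.to_dict() for f in self.inner_folds],
            "val_performance": None if self.val_performance is None
            else float(self.val_performance),
            "completed_folds": self.completed_folds,
            "incomplete": self.incomplete,
            "failed": self.failed,
            "error": self.error,
            "computation_time": self.computation_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfigEvaluation":
        return cls(
            Config.from_dict(d["config"]),
            [InnerFoldRecord.from_dict(f) for f in d["inner_folds"]],
            d["val_performance"], d["completed_folds"], d["incomplete"],
            d["failed"], d.get("error"), d.get("computation_time", 0.0),
        )


@dataclass
class OuterFoldResult:
    fold_id: int
    train_indices: list
    test_indices: list
    baseline: dict = field(default_factory=dict)
    tested_configs: list = field(default_factory=list)
    best_config: Optional[Config] = None
    train_metrics: dict = field(default_factory=dict)  # refit on outer-train
    test_metrics: dict = field(default_factory=dict)

    def index_digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.train_indices, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(self.test_indices, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "train_indices": [int(i) for i in self.train_indices],
            "test_indices": [int(i) for i in self.test_indices],
            "index_digest": self.index_digest(),
            "baseline": _metric_dict(self.baseline),
            "tested_configs": [c.to_dict() for c in self.tested_configs],
            "best_config": None if self.best_config is None else self.best_config.to_dict(),
            "train_metrics": _metric_dict(self.train_metrics),
            "test_metrics": _metric_dict(self.test_metrics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OuterFoldResult":
        return cls(
            d["fold_id"], d["train_indices"], d["test_indices"], d["baseline"],
            [ConfigEvaluation.from_dict(c) for c in d["tested_configs"]],
            None if d["best_config"] is None else Config.from_dict(d["best_config"]),
            d.get("train_metrics", {}), d.get("test_metrics", {}),
        )


@dataclass
class ResultTree:
    """Nested record of a full training/optimization/testing run."""

    name: str
    best_config_metric: str
    metrics: list
    spec_echo: dict = field(default_factory=dict)
    outer_folds: list = field(default_factory=list)
    overall_best_config: Optional[Config] = None
    created: str = ""
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "created": self.created,
            "best_config_metric": self.best_config_metric,
            "metrics": list(self.metrics),
            "spec_echo": self.spec_echo,
            "outer_folds": [f.to_dict() for f in self.outer_folds],
            "overall_best_config": None if self.overall_best_config is None
            else self.overall_best_config.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultTree":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"result schema {d.get('schema_version')!r} does not match "
                f"supported version {SCHEMA_VERSION!r}")
        return cls(
            name=d["name"],
            best_config_metric=d["best_config_metric"],
            metrics=d["metrics"],
            spec_echo=d.get("spec_echo", {}),
            outer_folds=[OuterFoldResult.from_dict(f) for f in d["outer_folds"]],
            overall_best_config=None if d["overall_best_config"] is None
            else Config.from_dict(d["overall_best_config"]),
            created=d.get("created", ""),
            schema_version=d["schema_version"],
        )

    def comparable_dict(self) -> dict:
        """The tree as a dict with wall-clock fields (timestamps and
        computation times) stripped — the deterministic content."""
        d = self.to_dict()
        d.pop("created", None)
        for f in d["outer_folds"]:
            for c in f["tested_configs"]:
                c.pop("computation_time", None)
        return d


def write_results(tree: ResultTree, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(tree.to_dict(), indent=2, sort_keys=True))
    return path


def read_results(path) -> ResultTree:
    return ResultTree.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Model archive (.photon)
# ---------------------------------------------------------------------------


def _describe_element(el) -> dict:
    if isinstance(el, PipelineElement):
        return {"type": "element", "name": el.name, "keyword": el.keyword,
                "fixed_params": {k: repr(v) for k, v in el.fixed_params.items()}}
    if isinstance(el, CallbackElement):
        return {"type": "callback", "name": el.name}
    kids = getattr(el, "children", None) or getattr(el, "elements", None) or []
    return {"type": type(el).__name__.lower(), "name": el.name,
            "children": [_describe_element(c) for c in kids]}


def _collect_keywords(el) -> list:
    if isinstance(el, PipelineElement):
        return [el.keyword]
    out = []
    for c in getattr(el, "children", None) or getattr(el, "elements", None) or []:
        out.extend(_collect_keywords(c))
    return out


def save_model(fitted, path, metric_summary: dict | None = None) -> Path:
    """Persist a fitted pipeline as a single self-contained ``.photon``
    archive (manifest + fitted state + integrity checksum)."""
    path = Path(path)
    if path.suffix != ".photon":
        path = path.with_suffix(".photon")
    path.parent.mkdir(parents=True, exist_ok=True)

    state = pickle.dumps(fitted, protocol=4)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "structure": [_describe_element(e) for e in fitted.elements],
        "keywords": sorted({k for e in fitted.elements for k in _collect_keywords(e)}),
        "config": fitted.config.to_dict(),
        "n_features_in": fitted.n_features_in,
        "feature_names": fitted.feature_names,
        "target_name": fitted.target_name,
        "metric_summary": metric_summary or {},
    }
    manifest_bytes = json.dumps(manifest, indent=2, sort_keys=True).encode()
    checksum = hashlib.sha256(manifest_bytes + state).hexdigest()

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", manifest_bytes)
        zf.writestr("state.pkl", state)
        zf.writestr("checksum.json", json.dumps({"sha256": checksum}))
    return path


def read_manifest(path) -> dict:
    with zipfile.ZipFile(path) as zf:
        return json.loads(zf.read("manifest.json"))


def load_model(path):
    """Load a ``.photon`` archive; verifies the checksum and that every
    element keyword is resolvable in the registry before unpickling."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest_bytes = zf.read("manifest.json")
            state = zf.read("state.pkl")
            stored = json.loads(zf.read("checksum.json"))["sha256"]
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ArchiveError(f"{path} is not a valid model archive: {exc}") from exc

    actual = hashlib.sha256(manifest_bytes + state).hexdigest()
    if actual != stored:
        raise ArchiveError(
            f"checksum mismatch in {path}: archive is corrupted or tampered with")

    manifest = json.loads(manifest_bytes)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ArchiveError(
            f"archive schema {manifest.get('schema_version')!r} does not match "
            f"supported version {SCHEMA_VERSION!r}")
    for kw in manifest.get("keywords", []):
        try:
            resolve(kw)
        except RegistrationError:
            raise ArchiveError(
                f"archive requires unregistered element keyword {kw!r}") from None
    return pickle.loads(state)


# ---------------------------------------------------------------------------
# Transform cache
# ---------------------------------------------------------------------------


def dataset_fingerprint(data) -> str:
    """Content digest of a DataTriple (row-major feature/target bytes)."""
    h = hashlib.sha256()
    X = np.ascontiguousarray(np.asarray(data.features, dtype=float))
    h.update(X.tobytes())
    h.update(b"|y|")
    if data.targets is not None:
        h.update(np.ascontiguousarray(np.asarray(data.targets)).tobytes())
    h.update(b"|sc|")
    if data.side_channel is not None:
        h.update(data.side_channel.to_csv(index=False).encode())
    return h.hexdigest()


def transform_cache_key(cache_ctx: dict, position: int, element, config_sig) -> str:
    """Digest identifying one element's fit+transform on one training set
    under one (element + upstream) configuration."""
    payload = repr((
        cache_ctx["fingerprint"],
        tuple(int(i) for i in cache_ctx["train_indices"]),
        position,
        element.keyword,
        tuple(sorted((k, repr(v)) for k, v in element.fixed_params.items())),
        config_sig,
    ))
    return hashlib.sha256(payload.encode()).hexdigest()


class Cache:
    """Directory-backed store of ``(fitted element, transformed output)``
    blobs; corrupt entries are recomputed and overwritten with a warning."""

    def __init__(self, folder):
        self.folder = Path(folder)
        self.folder.mkdir(parents=True, exist_ok=True)
        self.hits = 0
        self.misses = 0

    def _path(self, key: str) -> Path:
        return self.folder / f"{key}.pkl"

    def get(self, key: str):
        p = self._path(key)
        if not p.exists():
            self.misses += 1
            return None
        try:
            with open(p, "rb") as fh:
                value = pickle.load(fh)
        except Exception:  # noqa: BLE001
            warnings.warn(f"corrupted cache entry {p.name}; recomputing", stacklevel=2)
            p.unlink(missing_ok=True)
            self.misses += 1
            return None
        self.hits += 1
        return value

    def put(self, key: str, value) -> None:
        with open(self._path(key), "wb") as fh:
            pickle.dump(value, fh, protocol=4)
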