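"""Tabular I/O, feature encoding and the weighted-dataset container.

A :class:`WeightedDataset` holds one cohort: an encoded numeric feature
matrix, one nonnegative weight per row, stable row identifiers and an
optional target column that is *excluded* from the features (it is only
used for bias monitoring and downstream evaluation, never for weighting).

Encoding is schema-driven so that a representative cohort R and a
non-representative cohort N always live in the same feature space:
categorical columns are one-hot encoded in the schema-declared category
order, and a category absent from one cohort simply yields an all-zero
indicator column there.  Rows with any missing value in a declared column
are dropped at load time (listwise deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyDataError, SchemaError

logger = logging.getLogger(__name__)

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single input column."""

    name: str
    kind: str  # "numeric" | "categorical"
    categories: tuple = ()  # declared order; required for categorical

    def __post_init__(self):
        if self.kind not in (NUMERIC, CATEGORICAL):
            raise ConfigError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL and len(self.categories) == 0:
            raise ConfigError(f"categorical feature {self.name!r} needs declared categories")


@dataclass(frozen=True)
class Schema:
    """Ordered feature declarations shared by both cohorts."""

    features: tuple

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate feature names in schema")

    @property
    def names(self):
        return [f.name for f in self.features]

    def encoded_names(self):
        out = []
        for f in self.features:
            if f.kind == NUMERIC:
                out.append(f.name)
            else:
                out.extend(f"{f.name}={c}" for c in f.categories)
        return out

    def numeric_encoded_columns(self):
        """Indices of encoded columns that came from numeric features."""
        idx, j = [], 0
        for f in self.features:
            if f.kind == NUMERIC:
                idx.append(j)
                j += 1
            else:
                j += len(f.categories)
        return idx

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        """Encode a complete (no-missing) frame into the numeric matrix."""
        blocks = []
        for f in self.features:
            col = df[f.name]
            if f.kind == NUMERIC:
                try:
                    blocks.append(col.to_numpy(dtype=float).reshape(-1, 1))
                except (TypeError, ValueError) as exc:
                    raise SchemaError(f"column {f.name!r} is not numeric: {exc}") from exc
            else:
                vals = col.astype(object).to_numpy()
                unknown = set(vals) - set(f.categories)
                if unknown:
                    raise SchemaError(
                        f"column {f.name!r} has undeclared categories: {sorted(map(str, unknown))}"
                    )
                block = np.zeros((len(df), len(f.categories)))
                for j, c in enumerate(f.categories):
                    block[:, j] = vals == c
                blocks.append(block)
        if not blocks:
            raise ConfigError("schema declares no features")
        return np.hstack(blocks)


@dataclass
class WeightedDataset:
    """One cohort: encoded features, per-row weights, ids, optional target."""

    features: np.ndarray
    weights: np.ndarray
    ids: np.ndarray
    schema: Schema
    target: np.ndarray | None = None
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if n == 0:
            raise EmptyDataError("dataset has zero rows")
        self.weights = np.asarray(self.weights, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.target is not None:
            self.target = np.asarray(self.target)
            if len(self.target) != n:
                raise SchemaError("target length mismatch")
        if len(self.weights) != n or len(self.ids) != n:
            raise SchemaError("weights/ids length mismatch")
        if np.any(self.weights < 0):
            raise SchemaError("weights must be nonnegative")
        if np.any(~np.isfinite(self.features)):
            raise SchemaError("features contain non-finite values")
        if len(np.unique(self.ids)) != n:
            raise SchemaError("row ids must be unique")
        if not self.feature_names:
            self.feature_names = self.schema.encoded_names()

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def take(self, indices) -> "WeightedDataset":
        """Row subset preserving ids, weights and target."""
        indices = np.asarray(indices)
        return replace(
            self,
            features=self.features[indices],
            weights=self.weights[indices],
            ids=self.ids[indices],
            target=None if self.target is None else self.target[indices],
        )

    def with_weights(self, weights) -> "WeightedDataset":
        return replace(self, weights=np.asarray(weights, dtype=float))


def load_dataset(path, schema: Schema, target_name: str | None = None) -> WeightedDataset:
    """Load a CSV, drop incomplete rows, encode, initialize unit weights.

    Row ids are assigned from the input row order (0-based, counted before
    the missing-value filter) so weight files map back to input rows.
    """
    df = pd.read_csv(path)
    required = list(schema.names)
    if target_name is not None:
        required.append(target_name)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"declared columns missing from {path}: {missing}")
    df = df[required]
    df.index = np.arange(len(df))
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("dropped %d incomplete rows from %s", n_dropped, path)
    if len(complete) == 0:
        raise EmptyDataError(f"no complete rows left in {path}")
    logger.info("loaded %d rows from %s", len(complete), path)
    features = schema.encode(complete)
    target = complete[target_name].to_numpy() if target_name is not None else None
    return WeightedDataset(
        features=features,
        weights=np.ones(len(complete)),
        ids=complete.index.to_numpy(),
        schema=schema,
        target=target,
    )


def write_weights(ds: WeightedDataset, path) -> None:
    """Write the (id, weight) table; zero-weight rows are kept addressable."""
    out = pd.DataFrame({"id": ds.ids, "weight": ds.weights})
    out.to_csv(path, index=False)


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path)


def schema_from_config(cfg: dict) -> tuple:
    """Build (Schema, target_name) from a flat config mapping.

    Expected keys: ``features`` (ordered name -> kind mapping),
    ``categories`` (name -> list, for categorical features) and
    optionally ``target``.
    """
    if "features" not in cfg:
        raise ConfigError("config lacks a 'features' mapping")
    cats = cfg.get("categories", {}) or {}
    specs = []
    for name, kind in cfg["features"].items():
        if kind == CATEGORICAL:
            if name not in cats:
                raise ConfigError(f"categorical feature {name!r} has no declared categories")
            specs.append(FeatureSpec(name, CATEGORICAL, tuple(cats[name])))
        else:
            specs.append(FeatureSpec(name, kind))
    return Schema(tuple(specs)), cfg.get("target")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
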