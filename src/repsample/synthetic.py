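"""Synthetic population generator and artificial selection-bias injectors.

The generator emulates the kind of tabular survey/census data the
weighters target: a latent two-group population with correlated numeric
features, a categorical feature whose level frequencies differ between
groups, and a binary target drawn from a logistic model on the encoded
features (so the target is *predictable from*, but not identical to, the
features — the property that lets reweighting on features move a hidden
target toward its representative mean).

Two bias mechanisms mirror the evaluation protocol:

* mean-distance bias — row i is kept with probability proportional to
  exp(-strength * ||x_i - xbar||^3) (normalized so the mode has
  probability 1), i.e. rows far from the sample mean are under-selected;
* class-ratio bias — only ``keep_fraction`` of one target class is kept,
  all rows of the other class survive.

Both injectors return a row subset plus a :class:`BiasSpec` that records
the mechanism, strength and seed — enough to regenerate the subset
exactly and to serve as ground truth in recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureSpec, Schema, WeightedDataset
from .errors import ConfigError, SchemaError

MEAN_DISTANCE = "mean_distance"
CLASS_RATIO = "class_ratio"
NONE = "none"


@dataclass(frozen=True)
class BiasSpec:
    """Which artificial-bias mechanism was applied, and how."""

    mechanism: str
    strength: float
    biased_class: object = None
    seed: int | None = None

    def __post_init__(self):
        if self.mechanism not in (MEAN_DISTANCE, CLASS_RATIO, NONE):
            raise ConfigError(f"unknown bias mechanism {self.mechanism!r}")
        if self.mechanism == CLASS_RATIO and not 0 < self.strength <= 1:
            raise ConfigError("class-ratio keep fraction must lie in (0, 1]")


@dataclass
class PopulationSpec:
    """Mixture population with a logistic binary target.

    ``numeric_means`` has one row per latent group; ``numeric_covs`` is a
    per-group covariance (None = identity).  ``categorical`` maps feature
    name -> (categories, per-group probability rows).  ``target_coefs``
    are log-odds coefficients over the *encoded* feature vector.
    """

    n: int
    class_probs: tuple = (0.5, 0.5)
    numeric_means: tuple = ((0.0, 0.0, 0.0, 0.0), (1.0, 0.5, -0.5, 0.25))
    numeric_covs: tuple | None = None
    categorical: dict = field(
        default_factory=lambda: {
            "group": (("a", "b", "c"), ((0.5, 0.3, 0.2), (0.2, 0.3, 0.5)))
        }
    )
    target_coefs: tuple = (1.2, 0.8, -0.8, 0.5, 0.6, 0.0, -0.6)
    target_intercept: float = -0.8
    target_name: str = "outcome"
    seed: int = 0

    def validate(self):
        if self.n < 1:
            raise ConfigError("population size must be >= 1")
        probs = np.asarray(self.class_probs, dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("class probabilities must be nonnegative and sum to 1")
        means = np.asarray(self.numeric_means, dtype=float)
        if means.ndim != 2 or means.shape[0] != len(probs):
            raise ConfigError("numeric_means needs one row per latent group")
        if self.numeric_covs is not None:
            for cov in self.numeric_covs:
                cov = np.asarray(cov, dtype=float)
                if np.any(np.linalg.eigvalsh(cov) < -1e-10):
                    raise ConfigError("covariance matrices must be PSD")
        for name, (cats, rows) in self.categorical.items():
            rows = np.asarray(rows, dtype=float)
            if rows.shape != (len(probs), len(cats)):
                raise ConfigError(f"categorical {name!r}: wrong probability shape")
            if np.any(rows < 0) or not np.allclose(rows.sum(axis=1), 1.0):
                raise ConfigError(f"categorical {name!r}: rows must sum to 1")

    def schema(self) -> Schema:
        specs = [FeatureSpec(f"x{j + 1}", "numeric") for j in range(len(self.numeric_means[0]))]
        specs += [
            FeatureSpec(name, "categorical", tuple(cats))
            for name, (cats, _) in self.categorical.items()
        ]
        return Schema(tuple(specs))


def strong_coupling_spec(n: int, seed: int = 0) -> PopulationSpec:
    """Population whose target is strongly determined by the features.

    Used for class-ratio-bias recovery experiments.  Selection on the
    outcome shifts p(y|x) as well as p(x); covariate reweighting can only
    remove the p(x) part, so the attainable correction is capped by how
    much of y is explained by x.  The default coefficients (5x the base
    log-odds) put that cap at roughly 25% of the uniform-weights relative
    bias under keep-10% class-ratio selection, so the experiment measures
    the algorithm rather than the information-theoretic limit.
    """
    base = np.array([1.2, 0.8, -0.8, 0.5, 0.6, 0.0, -0.6])
    return PopulationSpec(
        n=n,
        seed=seed,
        target_coefs=tuple(base * 5.0),
        target_intercept=-4.0,
    )


def population_frame(spec: PopulationSpec) -> pd.DataFrame:
    """Draw the raw (unencoded) population table, target column included."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = rng.choice(len(spec.class_probs), size=spec.n, p=spec.class_probs)
    means = np.asarray(spec.numeric_means, dtype=float)
    d = means.shape[1]
    cols = {}
    numeric = np.empty((spec.n, d))
    for g in range(len(spec.class_probs)):
        mask = groups == g
        if not mask.any():
            continue
        cov = np.eye(d) if spec.numeric_covs is None else np.asarray(spec.numeric_covs[g])
        numeric[mask] = rng.multivariate_normal(means[g], cov, size=int(mask.sum()))
    for j in range(d):
        cols[f"x{j + 1}"] = numeric[:, j]
    for name, (cats, rows) in spec.categorical.items():
        rows = np.asarray(rows, dtype=float)
        values = np.empty(spec.n, dtype=object)
        for g in range(len(spec.class_probs)):
            mask = groups == g
            if mask.any():
                values[mask] = rng.choice(cats, size=int(mask.sum()), p=rows[g])
        cols[name] = values
    df = pd.DataFrame(cols)
    encoded = spec.schema().encode(df)
    coefs = np.asarray(spec.target_coefs, dtype=float)
    if coefs.shape != (encoded.shape[1],):
        raise ConfigError(
            f"target_coefs length {len(coefs)} != encoded width {encoded.shape[1]}"
        )
    logits = spec.target_intercept + encoded @ coefs
    df[spec.target_name] = (rng.random(spec.n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return df


def generate_population(spec: PopulationSpec) -> WeightedDataset:
    """Draw an i.i.d. population as an encoded, unit-weight dataset."""
    df = population_frame(spec)
    schema = spec.schema()
    return WeightedDataset(
        features=schema.encode(df),
        weights=np.ones(len(df)),
        ids=np.arange(len(df)),
        schema=schema,
        target=df[spec.target_name].to_numpy(),
    )


def _scaled_features(ds: WeightedDataset) -> np.ndarray:
    """Z-score numeric columns in place; one-hot indicators stay unscaled."""
    F = ds.features.copy()
    num = ds.schema.numeric_encoded_columns()
    if num:
        num = np.asarray(num)
        mu = F[:, num].mean(axis=0)
        sd = F[:, num].std(axis=0)
        sd[sd == 0] = 1.0
        F[:, num] = (F[:, num] - mu) / sd
    return F


def inject_mean_distance_bias(ds: WeightedDataset, strength: float = 0.05, seed=None,
                              max_retries: int = 10):
    """Keep rows with probability proportional to exp(-strength * ||x - xbar||^3).

    Selection probabilities are anchored so the row nearest the mean has
    probability ~1; each row is then an independent coin flip.  An empty
    draw is retried with a derived seed up to ``max_retries`` times.
    """
    if not strength > 0:
        raise ConfigError("mean-distance bias strength must be positive")
    F = _scaled_features(ds)
    dist = np.linalg.norm(F - F.mean(axis=0), axis=1)
    p = np.exp(-strength * dist**3)
    p = p / p.max()
    children = np.random.SeedSequence(seed).spawn(max_retries)
    for child in children:
        rng = np.random.default_rng(child)
        keep = np.flatnonzero(rng.random(ds.n) < p)
        if len(keep) > 0:
            return ds.take(keep), BiasSpec(MEAN_DISTANCE, strength, seed=seed)
    raise ConfigError("mean-distance bias retained no rows after retries")


def mean_distance_retention_probs(ds: WeightedDataset, strength: float = 0.05) -> np.ndarray:
    """The normalized per-row retention probabilities (for inspection)."""
    F = _scaled_features(ds)
    dist = np.linalg.norm(F - F.mean(axis=0), axis=1)
    p = np.exp(-strength * dist**3)
    return p / p.max()


def inject_class_ratio_bias(ds: WeightedDataset, biased_class, keep_fraction: float = 0.1,
                            seed=None):
    """Keep a uniform random fraction of one target class, all of the other."""
    if ds.target is None:
        raise SchemaError("class-ratio bias needs a target column")
    if not 0 < keep_fraction <= 1:
        raise ConfigError("keep_fraction must lie in (0, 1]")
    mask = ds.target == biased_class
    if not mask.any():
        raise SchemaError(f"biased class {biased_class!r} absent from the target")
    idx_class = np.flatnonzero(mask)
    n_keep = max(1, int(round(keep_fraction * len(idx_class))))
    rng = np.random.default_rng(seed)
    kept_class = rng.choice(idx_class, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(~mask), kept_class]))
    return ds.take(keep), BiasSpec(CLASS_RATIO, keep_fraction, biased_class, seed)


def uniform_subsample(ds: WeightedDataset, size: int, seed=None) -> WeightedDataset:
    """Same-size unbiased control subsample (for bias-signal sanity checks)."""
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(ds.n, size=size, replace=False))
    return ds.take(keep)
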