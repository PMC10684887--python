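"""RBF kernel, bandwidth heuristic and empirical maximum mean discrepancy.

The empirical MMD between samples X (size m) and Y (size n) is the
V-statistic form

    MMD(X, Y) = [ 1/m^2 sum_ij K(x_i, x_j)
                  - 2/(mn) sum_ij K(x_i, y_j)
                  + 1/n^2 sum_ij K(y_i, y_j) ]^(1/2)

with the RBF kernel K(x, y) = exp(-||x - y||^2 / (2 sigma^2)).  Within-set
sums deliberately include self-pairs, which keeps the bracket nonnegative
up to round-off; tiny negative round-off is clamped to zero before the
square root.

The bandwidth sigma is set heuristically to the mean Euclidean distance
over all unordered distinct pairs of the *aggregated* sample (X and Y
pooled).  Self-distances are excluded: including the zero diagonal would
systematically shrink sigma.

The weighted variant replaces Y's empirical mean embedding with a
weighted mean embedding (weights normalized to sum 1).  It reduces
exactly to the unweighted form under uniform weights and is invariant to
positive rescaling of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateBandwidthError, DegenerateWeightsError, EmptyDataError

AGGREGATED_MEAN_DISTANCE = "aggregated_mean_distance"
FIXED = "fixed"


@dataclass(frozen=True)
class KernelSpec:
    """RBF bandwidth plus the rule that produced it."""

    sigma: float
    rule: str = FIXED

    def __post_init__(self):
        if not self.sigma > 0:
            raise DegenerateBandwidthError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class MMDValue:
    value: float
    sigma_used: float
    weighted: bool


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    return X


def sigma_heuristic(X, Y=None) -> float:
    """Mean pairwise distance over the pooled sample (distinct pairs only)."""
    X = _as_matrix(X)
    Z = X if Y is None else np.vstack([X, _as_matrix(Y)])
    if Z.shape[0] < 2:
        raise EmptyDataError("bandwidth heuristic needs at least 2 pooled rows")
    sigma = float(pdist(Z).mean())
    if sigma <= 0.0:
        raise DegenerateBandwidthError("all pooled points identical; mean distance is 0")
    return sigma


def rbf(x, y, sigma: float) -> float:
    """RBF kernel value for a single pair of vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if not sigma > 0:
        raise DegenerateBandwidthError(f"sigma must be positive, got {sigma}")
    d2 = float(np.dot(x - y, x - y))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def rbf_matrix(A, B, sigma: float) -> np.ndarray:
    A, B = _as_matrix(A), _as_matrix(B)
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))


def _resolve_sigma(X, Y, kernel) -> float:
    if kernel is None:
        return sigma_heuristic(X, Y)
    if isinstance(kernel, KernelSpec):
        return kernel.sigma
    return float(kernel)


def mmd(X, Y, kernel: KernelSpec | float | None = None) -> MMDValue:
    """Unweighted empirical MMD; ``kernel=None`` applies the sigma heuristic."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise EmptyDataError("MMD needs nonempty samples on both sides")
    sigma = _resolve_sigma(X, Y, kernel)
    kxx = rbf_matrix(X, X, sigma).mean()
    kxy = rbf_matrix(X, Y, sigma).mean()
    kyy = rbf_matrix(Y, Y, sigma).mean()
    sq = kxx - 2.0 * kxy + kyy
    return MMDValue(float(np.sqrt(max(sq, 0.0))), sigma, weighted=False)


def weighted_mmd(X, Y, wY, kernel: KernelSpec | float | None = None) -> MMDValue:
    """MMD with Y's mean embedding replaced by the wY-weighted embedding."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise EmptyDataError("MMD needs nonempty samples on both sides")
    wY = np.asarray(wY, dtype=float)
    if wY.shape != (Y.shape[0],):
        raise ValueError("wY must be one weight per Y row")
    if np.any(wY < 0):
        raise DegenerateWeightsError("weights must be nonnegative")
    total = wY.sum()
    if total <= 0:
        raise DegenerateWeightsError("all-zero weights")
    w = wY / total
    sigma = _resolve_sigma(X, Y, kernel)
    kxx = rbf_matrix(X, X, sigma).mean()
    kxy = rbf_matrix(X, Y, sigma).mean(axis=0) @ w
    kyy = w @ rbf_matrix(Y, Y, sigma) @ w
    sq = kxx - 2.0 * kxy + kyy
    return MMDValue(float(np.sqrt(max(sq, 0.0))), sigma, weighted=True)


class WeightedMMDScorer:
    """Precomputed kernel pieces for repeated weighted-MMD evaluation.

    Used by the iterative reweighter, where X (the reference cohort) and Y
    (the biased cohort) are fixed and only the weights change: each
    evaluation is then a quadratic form instead of fresh kernel matrices.
    """

    def __init__(self, X, Y, sigma: float):
        X, Y = _as_matrix(X), _as_matrix(Y)
        if not sigma > 0:
            raise DegenerateBandwidthError(f"sigma must be positive, got {sigma}")
        self.sigma = float(sigma)
        self._kxx_mean = rbf_matrix(X, X, sigma).mean()
        self._kxy_colmean = rbf_matrix(X, Y, sigma).mean(axis=0)
        self._kyy = rbf_matrix(Y, Y, sigma)

    def __call__(self, wY) -> float:
        wY = np.asarray(wY, dtype=float)
        total = wY.sum()
        if total <= 0:
            raise DegenerateWeightsError("all-zero weights")
        w = wY / total
        sq = self._kxx_mean - 2.0 * (self._kxy_colmean @ w) + w @ self._kyy @ w
        return float(np.sqrt(max(sq, 0.0)))


def joint_zscore(X, Y, columns=None):
    """Z-score both matrices with mean/sd of the pooled sample.

    Kernel distances are scale-sensitive, so standardization always pools
    the two cohorts; constant columns keep unit scale.  ``columns`` limits
    standardization to a subset (e.g. numeric columns, leaving one-hot
    indicators untouched).
    """
    X, Y = _as_matrix(X).copy(), _as_matrix(Y).copy()
    Z = np.vstack([X, Y])
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    if columns is None:
        return (X - mu) / sd, (Y - mu) / sd
    cols = np.asarray(columns, dtype=int)
    X[:, cols] = (X[:, cols] - mu[cols]) / sd[cols]
    Y[:, cols] = (Y[:, cols] - mu[cols]) / sd[cols]
    return X, Y
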