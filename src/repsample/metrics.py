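"""Evaluation statistics: relative bias, AUROC/AUPRC, Wasserstein, mean ranks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wasserstein_distance
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import MetricError


@dataclass
class EvaluationRecord:
    """One (method, dataset, trial) evaluation row."""

    method: str
    dataset: str
    trial: int
    auroc: float = np.nan
    auprc: float = np.nan
    mmd: float = np.nan
    relative_bias: float = np.nan


def relative_bias(rep_mean, values, weights=None) -> float:
    """Percent deviation of the weighted mean from the representative mean:
    |(Ybar - ybar_w) / Ybar| * 100.  Invariant to rescaling the weights."""
    if rep_mean == 0:
        raise MetricError("relative bias undefined for a zero representative mean")
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise MetricError("weights must have positive total mass")
    ybar = np.average(values, weights=weights)
    return float(abs((rep_mean - ybar) / rep_mean) * 100.0)


def _check_binary(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("metric undefined: labels contain a single class")
    return labels


def auroc(labels, scores) -> float:
    """Rank-based AUROC; ties count one half."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = np.asarray(labels)
    if np.sum(labels == np.max(labels)) == 0 or len(np.unique(labels)) < 2:
        raise MetricError("AUPRC undefined without positive labels")
    return float(average_precision_score(labels, scores))


def wasserstein_1d(a, b, a_weights=None, b_weights=None) -> float:
    """L1 distance between (weighted) empirical quantile functions."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise MetricError("Wasserstein distance needs nonempty samples")
    return float(wasserstein_distance(a, b, u_weights=a_weights, v_weights=b_weights))


def mean_ranks(table: pd.DataFrame, higher_is_better: bool = True) -> pd.Series:
    """Mean rank per method over datasets (rows: methods, columns: datasets).

    Rank 1 is best within each dataset; exact ties receive the average of
    the ranks they span.
    """
    if table.isna().any().any():
        raise MetricError("rank table has missing cells")
    sign = -1.0 if higher_is_better else 1.0
    ranks = table.apply(lambda col: rankdata(sign * col.to_numpy()), axis=0)
    return ranks.mean(axis=1)
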