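"""Experiment orchestration: trajectory runs, method comparison, downstream demos.

Three protocols are provided:

* :func:`run_trajectory` runs MRS to exhaustion (one drop at a time past
  the usual stopping rule) and records AUROC, MMD and — when a held-out
  target is available — the relative bias of that hidden column at every
  iteration, repeated over seeds.
* :func:`run_comparison` benchmarks weighters end to end: split a
  population 50/50, inject mean-distance selection bias into the training
  half, fit each method's weights with the (target-free) biased half
  against the test half, train a cost-complexity-pruned tree on the
  weighted biased half, and score AUROC/AUPRC on the test half; weighted
  MMD and target relative bias are recorded alongside.  No weighting
  method ever sees the target column.
* :func:`weighted_logistic_lrt` is the downstream statistical demo: a
  weighted logistic regression with a likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.tree import DecisionTreeClassifier

from .data import WeightedDataset
from .errors import ConfigError, MetricError
from .metrics import EvaluationRecord, auprc, auroc, mean_ranks, relative_bias
from .mmd import joint_zscore, rbf_matrix, sigma_heuristic, weighted_mmd
from .mrs import MRS, select_ccp_alpha
from .records import TrajectoryRecord
from .soft_mrs import SoftMRS
from .baselines import KMMWeights, PSAWeights, UniformWeights


def _features(ds):
    return ds.features if hasattr(ds, "features") else np.asarray(ds, dtype=float)


class _MaskedMMD:
    """MMD of (R, active subset of N) for arbitrary masks, from one kernel pass.

    The bandwidth is frozen at iteration 0 (full N), so the MMD series of
    a shrinking active set stays comparable across iterations.
    """

    def __init__(self, Xr, Xn):
        Xr_s, Xn_s = joint_zscore(Xr, Xn)
        self.sigma = sigma_heuristic(Xr_s, Xn_s)
        self._kxx_mean = rbf_matrix(Xr_s, Xr_s, self.sigma).mean()
        self._kxy = rbf_matrix(Xr_s, Xn_s, self.sigma)
        self._kyy = rbf_matrix(Xn_s, Xn_s, self.sigma)

    def __call__(self, mask) -> float:
        idx = np.flatnonzero(mask)
        kxy = self._kxy[:, idx].mean()
        kyy = self._kyy[np.ix_(idx, idx)].mean()
        sq = self._kxx_mean - 2.0 * kxy + kyy
        return float(np.sqrt(max(sq, 0.0)))


def run_trajectory(R, N, repeats=10, seed=None, compute_mmd=True, freeze_sigma=True,
                   **mrs_params):
    """Run MRS to exhaustion ``repeats`` times, monitoring metrics per iteration.

    ``R`` and ``N`` are :class:`WeightedDataset` cohorts; when both carry
    a target column its relative bias (against R's mean) is tracked even
    though the weighters never see it.  Returns a list of per-repeat
    dicts with keys ``records`` (TrajectoryRecord list), ``stop_iteration``
    (where the standard AUROC rule would have stopped) and ``estimator``.
    """
    Xr, Xn = _features(R), _features(N)
    masked_mmd = _MaskedMMD(Xr, Xn) if compute_mmd else None
    rep_target = getattr(R, "target", None)
    non_target = getattr(N, "target", None)
    monitor_bias = rep_target is not None and non_target is not None
    rep_mean = float(np.mean(rep_target)) if monitor_bias else None

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        run_seed = int(rng.integers(2**31))
        est = MRS(exhaust=True, random_state=run_seed, **mrs_params)
        est.fit(Xn, Xr)
        mask = np.ones(len(Xn), dtype=bool)
        for rec in est.trajectory_:
            if compute_mmd:
                if not freeze_sigma:
                    sub = np.flatnonzero(mask)
                    rec.mmd = weighted_mmd(Xr, Xn[sub], np.ones(len(sub))).value
                else:
                    rec.mmd = masked_mmd(mask)
            if monitor_bias and rep_mean != 0:
                rec.relative_bias = relative_bias(rep_mean, non_target[mask])
            mask[rec.dropped_ids] = False
        out.append(
            {"records": est.trajectory_, "stop_iteration": est.stop_iteration_,
             "estimator": est}
        )
    return out


def default_method_factories(mrs_params=None, soft_params=None, kmm_params=None):
    """Name -> factory(seed) -> weighter, for the comparison harness."""
    mrs_params = dict(mrs_params or {})
    soft_params = dict(soft_params or {})
    kmm_params = dict(kmm_params or {})
    return {
        "uniform": lambda seed: UniformWeights(),
        "psa": lambda seed: PSAWeights(random_state=seed),
        "kmm": lambda seed: KMMWeights(**kmm_params),
        "mrs": lambda seed: MRS(random_state=seed, **mrs_params),
        "soft-mrs": lambda seed: SoftMRS(random_state=seed, **soft_params),
    }


@dataclass
class ComparisonReport:
    """Per-trial records plus recomputable aggregates."""

    records: list = field(default_factory=list)
    trials: int = 0
    dataset_sizes: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def summary(self) -> pd.DataFrame:
        df = self.frame()
        return df.groupby(["dataset", "method"])[
            ["auroc", "auprc", "mmd", "relative_bias"]
        ].agg(["mean", "std"])

    def mean_table(self, metric: str) -> pd.DataFrame:
        """Methods x datasets table of per-cell means for one metric."""
        df = self.frame()
        return df.pivot_table(index="method", columns="dataset", values=metric,
                              aggfunc="mean")

    def ranks(self, metric: str, higher_is_better: bool, min_size: int = 0) -> pd.Series:
        table = self.mean_table(metric)
        if min_size:
            keep = [d for d, n in self.dataset_sizes.items() if n > min_size]
            table = table[[c for c in table.columns if c in keep]]
        return mean_ranks(table, higher_is_better=higher_is_better)


def _downstream_tree_scores(N: WeightedDataset, weights, R: WeightedDataset, seed):
    """Pruned tree trained on the weighted biased half, scored on the test half."""
    y = np.asarray(N.target)
    alpha = select_ccp_alpha(N.features, y, seed=seed, sample_weight=np.asarray(weights))
    tree = DecisionTreeClassifier(ccp_alpha=alpha, random_state=seed)
    tree.fit(N.features, y, sample_weight=np.asarray(weights))
    pos = np.max(np.asarray(N.target))
    col = list(tree.classes_).index(pos)
    return tree.predict_proba(R.features)[:, col]


def _split_and_bias(ds: WeightedDataset, seed, subsample, bias_strength, min_biased):
    from .synthetic import inject_mean_distance_bias, uniform_subsample

    rng = np.random.default_rng(seed)
    work = ds
    if subsample and ds.n > subsample:
        work = uniform_subsample(ds, subsample, seed=int(rng.integers(2**31)))
    perm = rng.permutation(work.n)
    half = work.n // 2
    train = work.take(np.sort(perm[:half]))
    test = work.take(np.sort(perm[half:]))
    biased, _ = inject_mean_distance_bias(
        train, strength=bias_strength, seed=int(rng.integers(2**31))
    )
    ok = (
        len(np.unique(test.target)) == 2
        and len(np.unique(biased.target)) == 2
        and biased.n >= min_biased
        and np.mean(test.target) != 0
    )
    return test, biased, ok


def run_comparison(populations: dict, methods: dict, trials: int = 50, seed=None,
                   subsample: int = 5000, bias_strength: float = 0.05,
                   min_biased: int = 50, max_retries: int = 10) -> ComparisonReport:
    """Benchmark weighting methods on one or more synthetic populations.

    ``populations`` maps dataset name -> WeightedDataset with a binary
    target; ``methods`` maps method name -> factory(seed) -> weighter.
    Each trial draws a fresh 50/50 split, biases the training half with
    the mean-distance mechanism, computes every method's weights from the
    target-free feature matrices, and evaluates the weighted downstream
    tree on the untouched test half.  Degenerate splits (a single target
    class on either side) are resampled with a derived seed.
    """
    for name, ds in populations.items():
        if ds.target is None:
            raise ConfigError(f"population {name!r} has no target column")
    report = ComparisonReport(trials=trials,
                              dataset_sizes={k: v.n for k, v in populations.items()})
    root = np.random.default_rng(seed)
    for ds_name, ds in populations.items():
        for trial in range(trials):
            trial_seed = int(root.integers(2**31))
            test = biased = None
            for attempt in range(max_retries):
                test, biased, ok = _split_and_bias(
                    ds, trial_seed + attempt, subsample, bias_strength, min_biased
                )
                if ok:
                    break
            else:
                raise ConfigError(f"could not draw a usable split for {ds_name!r}")
            rep_mean = float(np.mean(test.target))
            Xr_s, Xn_s = joint_zscore(test.features, biased.features)
            sigma = sigma_heuristic(Xr_s, Xn_s)
            for m_name, factory in methods.items():
                method_seed = int(np.random.default_rng(trial_seed + 7).integers(2**31))
                weights = factory(method_seed).fit_weights(biased.features, test.features)
                scores = _downstream_tree_scores(biased, weights, test, method_seed)
                report.records.append(
                    EvaluationRecord(
                        method=m_name,
                        dataset=ds_name,
                        trial=trial,
                        auroc=auroc(test.target, scores),
                        auprc=auprc(test.target, scores),
                        mmd=weighted_mmd(Xr_s, Xn_s, weights, sigma).value,
                        relative_bias=relative_bias(rep_mean, biased.target, weights),
                    )
                )
    return report


def weighted_logistic_lrt(x, y, w=None):
    """Weighted logistic regression of y on x with a likelihood-ratio test.

    Returns (slope coefficient, LRT p-value); the statistic is
    2 * (loglik_full - loglik_null) on one chi-square degree of freedom.
    Invariant to splitting a row into duplicates with shared weight mass.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise MetricError("outcome must contain both classes")
    if w is None:
        w = np.ones_like(y)
    w = np.asarray(w, dtype=float)
    if w.sum() <= 0:
        raise MetricError("weights must have positive total mass")
    exog = sm.add_constant(x)
    family = sm.families.Binomial()
    full = sm.GLM(y, exog, family=family, freq_weights=w).fit(maxiter=200)
    null = sm.GLM(y, np.ones_like(y), family=family, freq_weights=w).fit(maxiter=200)
    stat = 2.0 * (full.llf - null.llf)
    p = float(chi2.sf(max(stat, 0.0), df=1))
    return float(full.params[1]), p


def export_ecdf_comparison(series: dict) -> pd.DataFrame:
    """Weighted ECDFs of named samples on the pooled support.

    ``series`` maps name -> values or (values, weights).  Returns a frame
    with column ``x`` (pooled sorted support) and one ECDF column per
    series; zero-weight rows carry no mass.
    """
    if not series:
        raise ConfigError("no series to export")
    parsed = {}
    support = []
    for name, entry in series.items():
        if isinstance(entry, tuple):
            values, weights = entry
        else:
            values, weights = entry, None
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ConfigError(f"series {name!r} is empty")
        weights = np.ones_like(values) if weights is None else np.asarray(weights, float)
        order = np.argsort(values, kind="stable")
        parsed[name] = (values[order], weights[order])
        support.append(values)
    grid = np.unique(np.concatenate(support))
    out = {"x": grid}
    for name, (v, w) in parsed.items():
        cum = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
        out[name] = cum[np.searchsorted(v, grid, side="right")]
    return pd.DataFrame(out)
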