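"""Maximal representative subsampling (MRS): iterative hard removal.

MRS treats bias correction as a positive-unlabeled discrimination
problem: a classifier is trained to tell the representative cohort R from
the non-representative cohort N.  Each iteration the ``drop_count`` active
N rows with the highest out-of-fold probability of belonging to N — the
most over-represented or atypical rows — get weight 0.  The loop stops
when a cost-complexity-pruned decision tree can no longer separate the
cohorts, i.e. when its out-of-fold AUROC is within ``delta`` of 0.5.

The retained rows keep weight exactly 1, so the result is a uniform
subsample that downstream methods can consume without weight support.

Two classifiers play distinct roles, both evaluated with stratified
5-fold cross-validation on the pooled cohorts:

* removal scores come from a random forest (fixed hyperparameters; the
  repeated refits make per-iteration tuning prohibitively expensive);
* the stopping check uses a single decision tree whose pruning strength
  ``ccp_alpha`` is chosen per fold by an internal cross-validation, and
  whose pooled out-of-fold scores give the AUROC.  Resubstitution AUROC
  of an unpruned tree would sit at ~1 and never trigger the stop.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .base import BaseWeighter
from .errors import ConfigError
from .records import TrajectoryRecord

REPRESENTATIVE, NON_REPRESENTATIVE = 0, 1


def _features(ds):
    return ds.features if hasattr(ds, "features") else np.asarray(ds, dtype=float)


def _check_folds(n_rep, n_non, folds):
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    if min(n_rep, n_non) < folds:
        raise ConfigError(
            f"cohort smaller than fold count: sizes ({n_rep}, {n_non}), folds {folds}"
        )


def oof_probabilities(R, N_active, folds=5, seed=None, n_estimators=25, min_samples_leaf=5):
    """Out-of-fold P(non-representative) for every active N row.

    R and the active N rows are pooled with cohort labels, split with a
    stratified k-fold on the label, and a random forest fitted per fold
    scores its held-out rows; each N row receives exactly one probability.
    """
    Xr, Xn = _features(R), _features(N_active)
    _check_folds(len(Xr), len(Xn), folds)
    X = np.vstack([Xr, Xn])
    y = np.concatenate([np.zeros(len(Xr), dtype=int), np.ones(len(Xn), dtype=int)])
    probs = np.full(len(X), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            min_samples_leaf=min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X[train_idx], y[train_idx])
        col = list(clf.classes_).index(NON_REPRESENTATIVE)
        probs[test_idx] = clf.predict_proba(X[test_idx])[:, col]
    return probs[len(Xr):]


def select_ccp_alpha(X, y, seed=None, sample_weight=None, max_alphas=6, inner_folds=3):
    """Pick a pruning strength by internal CV over the pruning path.

    Candidate alphas are a geometric subsample of the cost-complexity
    path (always including 0); the winner minimizes mean held-out
    misclassification.  Ties go to the *smaller* alpha: heavier pruning
    must strictly win, otherwise a root-only tree (whose scores are
    constant, AUROC exactly 0.5) could displace a genuinely
    discriminating subtree it merely ties with.
    """
    path = DecisionTreeClassifier(random_state=seed).cost_complexity_pruning_path(
        X, y, sample_weight=sample_weight
    )
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > 1:
        # the terminal path alpha collapses the tree to its root (constant
        # scores); pruning that far is never a useful stopping-check tree
        alphas = alphas[:-1]
    if len(alphas) > max_alphas:
        idx = np.unique(np.round(np.linspace(0, len(alphas) - 1, max_alphas)).astype(int))
        alphas = alphas[idx]
    if len(alphas) == 1:
        return float(alphas[0])
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(alphas))
    for tr, te in skf.split(X, y):
        sw_tr = None if sample_weight is None else sample_weight[tr]
        sw_te = None if sample_weight is None else sample_weight[te]
        for j, a in enumerate(alphas):
            tree = DecisionTreeClassifier(ccp_alpha=a, random_state=seed)
            tree.fit(X[tr], y[tr], sample_weight=sw_tr)
            pred = tree.predict(X[te])
            miss = pred != y[te]
            errors[j] += miss.mean() if sw_te is None else np.average(miss, weights=sw_te)
    best = int(np.flatnonzero(errors == errors.min())[0])  # tie -> smaller alpha
    return float(alphas[best])


def stopping_auroc(R, N_active, folds=5, seed=None):
    """AUROC of a cost-complexity-pruned tree from pooled out-of-fold scores."""
    Xr, Xn = _features(R), _features(N_active)
    _check_folds(len(Xr), len(Xn), folds)
    X = np.vstack([Xr, Xn])
    y = np.concatenate([np.zeros(len(Xr), dtype=int), np.ones(len(Xn), dtype=int)])
    scores = np.full(len(X), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        alpha = select_ccp_alpha(X[train_idx], y[train_idx], seed=seed)
        tree = DecisionTreeClassifier(ccp_alpha=alpha, random_state=seed)
        tree.fit(X[train_idx], y[train_idx])
        col = list(tree.classes_).index(NON_REPRESENTATIVE)
        scores[test_idx] = tree.predict_proba(X[test_idx])[:, col]
    return float(roc_auc_score(y, scores))


class MRS(BaseWeighter):
    """Iterative hard-removal weighter producing {0, 1} sample weights.

    Parameters
    ----------
    drop_count : int
        Rows removed per iteration (k).  Larger k is faster but coarser.
    delta : float
        AUROC tolerance of the stopping rule |AUROC - 0.5| <= delta.
    folds : int
        Stratified CV folds for both the removal scores and the stop check.
    min_active : int or None
        Floor on the active-set size; default ``max(2 * folds, 20)``.
    n_estimators, min_samples_leaf :
        Random-forest settings for the removal-score classifier.
    exhaust : bool
        When True the AUROC rule does not terminate the loop; the run
        continues until the active set cannot sustain the CV any more
        (trajectory studies).  The first iteration satisfying the rule is
        still recorded as ``stop_iteration_``.
    record_oof : bool
        Keep per-iteration out-of-fold scores in the trajectory.

    Attributes
    ----------
    weights_ : ndarray of {0.0, 1.0}
    trajectory_ : list of TrajectoryRecord
    n_iterations_, final_auroc_, stopped_by_, stop_iteration_
    """

    def __init__(
        self,
        drop_count=1,
        delta=0.001,
        folds=5,
        min_active=None,
        n_estimators=25,
        min_samples_leaf=5,
        random_state=None,
        exhaust=False,
        record_oof=False,
    ):
        self.drop_count = drop_count
        self.delta = delta
        self.folds = folds
        self.min_active = min_active
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.exhaust = exhaust
        self.record_oof = record_oof

    def fit(self, X, X_reference):
        X, R = self._validate_pair(X, X_reference)
        if self.drop_count < 1:
            raise ConfigError("drop_count must be >= 1")
        if not 0 < self.delta < 0.5:
            raise ConfigError("delta must be in (0, 0.5)")
        floor = self.min_active
        if floor is None:
            # exhaust mode defaults to the deepest floor the CV allows
            floor = self.folds if self.exhaust else max(2 * self.folds, 20)
        if floor < self.folds:
            raise ConfigError("min_active must be >= folds")
        n = len(X)
        if n <= floor and not self.exhaust:
            raise ConfigError(f"|N|={n} must exceed min_active={floor}")
        rng = np.random.default_rng(self.random_state)

        active = np.ones(n, dtype=bool)
        trajectory = []
        self.stop_iteration_ = None
        it = 0
        while True:
            seed_stop = int(rng.integers(2**31))
            seed_oof = int(rng.integers(2**31))
            active_idx = np.flatnonzero(active)
            auroc = stopping_auroc(R, X[active_idx], folds=self.folds, seed=seed_stop)
            rec = TrajectoryRecord(iteration=it, active_n=len(active_idx), auroc=auroc)
            trajectory.append(rec)
            within = abs(auroc - 0.5) <= self.delta
            if within and self.stop_iteration_ is None:
                self.stop_iteration_ = it
            if within and not self.exhaust:
                self.stopped_by_ = "auroc_within_delta"
                break
            if len(active_idx) - self.drop_count < floor:
                self.stopped_by_ = "exhausted" if self.exhaust else "min_active_reached"
                break
            probs = oof_probabilities(
                R,
                X[active_idx],
                folds=self.folds,
                seed=seed_oof,
                n_estimators=self.n_estimators,
                min_samples_leaf=self.min_samples_leaf,
            )
            if self.record_oof:
                rec.oof_scores = probs
            # stable argsort on -p: ties broken by input order
            order = np.argsort(-probs, kind="stable")
            dropped = active_idx[order[: self.drop_count]]
            active[dropped] = False
            rec.dropped_ids = dropped.tolist()
            it += 1

        self.weights_ = active.astype(float)
        self.trajectory_ = trajectory
        self.n_iterations_ = it
        self.final_auroc_ = trajectory[-1].auroc
        return self

    def active_mask_at(self, iteration: int) -> np.ndarray:
        """Reconstruct the active mask at the *start* of an iteration."""
        check_is_fitted(self, "trajectory_")
        mask = np.ones(len(self.weights_), dtype=bool)
        for rec in self.trajectory_:
            if rec.iteration >= iteration:
                break
            mask[rec.dropped_ids] = False
        return mask


def run_mrs(R, N, **params) -> MRS:
    """Functional wrapper: fit MRS on (reference R, biased N) datasets."""
    est = MRS(**params)
    est.fit(_features(N), _features(R))
    return est
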