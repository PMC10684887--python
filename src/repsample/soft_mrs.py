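"""Soft-MRS: iterative multiplicative reweighting of the biased cohort.

Instead of removing rows, Soft-MRS keeps every sample and adapts a
strictly positive weight per row.  Each iteration, for every candidate
tree size (a grid of minimum-weight-fraction-per-leaf values), a single
decision tree is fitted to distinguish the cohorts using the current
weights; each biased-cohort row then receives the multiplicative update

    w_i' = w_i * (0.5 + p_rep_i)

where ``p_rep_i`` is the tree's predicted probability that row i belongs
to the representative cohort — a confident representative-looking row
gains 50%, a confident non-representative row loses 50%, and p = 0.5
leaves the weight unchanged.  The candidate whose updated weights yield
the lowest weighted MMD against the reference cohort is committed
(greedy), and the loop stops once the best-so-far MMD has not improved
for ``patience`` consecutive iterations.

Weights are renormalized to mean 1 after every update: the weighted MMD
is invariant to positive rescaling, so this changes nothing the
optimizer sees while preventing multiplicative drift of the raw scale.
The kernel bandwidth is frozen at iteration 0 (aggregated-sample
heuristic on jointly standardized features) so the MMD trajectory is
comparable across iterations.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .base import BaseWeighter
from .errors import ConfigError
from .mmd import WeightedMMDScorer, joint_zscore, sigma_heuristic
from .records import TrajectoryRecord

REPRESENTATIVE, NON_REPRESENTATIVE = 0, 1


def _features(ds):
    return ds.features if hasattr(ds, "features") else np.asarray(ds, dtype=float)


def update_factor(p_rep):
    """Multiplicative weight update 0.5 + P(representative), in [0.5, 1.5]."""
    p = np.asarray(p_rep, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out = 0.5 + p
    return float(out) if np.isscalar(p_rep) else out


def _fit_candidate_tree(Xr, Xn, w, leaf_fraction, seed, balance_reference=True):
    X = np.vstack([Xr, Xn])
    y = np.concatenate([np.zeros(len(Xr), dtype=int), np.ones(len(Xn), dtype=int)])
    if balance_reference:
        rep_w = np.full(len(Xr), w.sum() / len(Xr))
    else:
        rep_w = np.ones(len(Xr))
    sw = np.concatenate([rep_w, w])
    tree = DecisionTreeClassifier(
        min_weight_fraction_leaf=leaf_fraction, random_state=seed
    )
    tree.fit(X, y, sample_weight=sw)
    col = list(tree.classes_).index(REPRESENTATIVE)
    p_rep = tree.predict_proba(Xn)[:, col]
    return p_rep


def candidate_update(R, N, w, leaf_fraction, seed=None, scorer=None, sigma=None,
                     balance_reference=True):
    """One hyperparameter candidate: tree fit, weight update, weighted MMD.

    The tree trains on all pooled rows (no cross-validation) with the
    reference cohort's total training weight balanced to match N's, and
    scores every N row from that same fit.  Returns the mean-1 normalized
    candidate weights and their weighted MMD against R.
    """
    Xr, Xn = _features(R), _features(N)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ConfigError("incoming weights must be strictly positive")
    p_rep = _fit_candidate_tree(Xr, Xn, w, leaf_fraction, seed, balance_reference)
    w_new = w * update_factor(p_rep)
    w_new *= len(w_new) / w_new.sum()  # mean 1
    if scorer is None:
        Xr_s, Xn_s = joint_zscore(Xr, Xn)
        if sigma is None:
            sigma = sigma_heuristic(Xr_s, Xn_s)
        scorer = WeightedMMDScorer(Xr_s, Xn_s, sigma)
    return w_new, scorer(w_new)


class SoftMRS(BaseWeighter):
    """Greedy multiplicative reweighter minimizing weighted MMD.

    Parameters
    ----------
    patience : int
        Consecutive non-improving iterations tolerated before stopping.
    leaf_fractions : sequence of float in [0, 0.5)
        Per-iteration candidate grid of minimum-weight-fraction-per-leaf
        values for the discriminating tree.
    max_iterations : int
        Hard cap on iterations.
    sigma : float or None
        RBF bandwidth; None applies the aggregated-sample heuristic on the
        jointly standardized cohorts, frozen at iteration 0.
    balance_reference : bool
        Scale the reference cohort's total training weight to match N's
        current total, so the tree cannot collapse onto the larger cohort.

    Attributes
    ----------
    weights_ : ndarray, strictly positive, mean 1 (best-so-far iterate)
    best_mmd_, best_iteration_, initial_mmd_, sigma_
    trajectory_ : list of TrajectoryRecord (iteration 0 = uniform start)
    stopped_by_ : {"patience_exhausted", "max_iterations"}
    """

    def __init__(
        self,
        patience=25,
        leaf_fractions=(0.01, 0.02, 0.05, 0.1, 0.2),
        max_iterations=500,
        sigma=None,
        balance_reference=True,
        random_state=None,
        record_weights=False,
    ):
        self.patience = patience
        self.leaf_fractions = leaf_fractions
        self.max_iterations = max_iterations
        self.sigma = sigma
        self.balance_reference = balance_reference
        self.random_state = random_state
        self.record_weights = record_weights

    def fit(self, X, X_reference):
        X, R = self._validate_pair(X, X_reference)
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        grid = tuple(self.leaf_fractions)
        if not grid or any(not 0 <= g < 0.5 for g in grid):
            raise ConfigError("leaf_fractions must be nonempty with values in [0, 0.5)")
        rng = np.random.default_rng(self.random_state)

        Xr_s, Xn_s = joint_zscore(R, X)
        sigma = self.sigma if self.sigma is not None else sigma_heuristic(Xr_s, Xn_s)
        scorer = WeightedMMDScorer(Xr_s, Xn_s, sigma)
        self.sigma_ = float(sigma)

        n = len(X)
        w = np.ones(n)
        mmd0 = scorer(w)
        self.initial_mmd_ = mmd0
        best_w, best_mmd, best_it = w.copy(), mmd0, 0
        trajectory = [
            TrajectoryRecord(
                iteration=0, active_n=n, mmd=mmd0, best_mmd=mmd0,
                weights=w.copy() if self.record_weights else None,
            )
        ]
        stall = 0
        stopped_by = "max_iterations"
        for it in range(1, self.max_iterations + 1):
            seed_it = int(rng.integers(2**31))
            candidates = []
            for g in grid:
                w_c, mmd_c = candidate_update(
                    R, X, w, g, seed=seed_it, scorer=scorer,
                    balance_reference=self.balance_reference,
                )
                candidates.append((mmd_c, w_c))
            cand_mmds = [c[0] for c in candidates]
            j = int(np.argmin(cand_mmds))  # tie -> first grid value
            w = candidates[j][1]
            committed = cand_mmds[j]
            if committed < best_mmd:
                best_w, best_mmd, best_it = w.copy(), committed, it
                stall = 0
            else:
                stall += 1
            trajectory.append(
                TrajectoryRecord(
                    iteration=it, active_n=n, mmd=committed, best_mmd=best_mmd,
                    candidate_mmds=list(cand_mmds),
                    weights=w.copy() if self.record_weights else None,
                )
            )
            if stall >= self.patience:
                stopped_by = "patience_exhausted"
                break

        self.weights_ = best_w
        self.best_mmd_ = best_mmd
        self.best_iteration_ = best_it
        self.trajectory_ = trajectory
        self.stopped_by_ = stopped_by
        return self


def run_soft_mrs(R, N, **params) -> SoftMRS:
    """Functional wrapper: fit Soft-MRS on (reference R, biased N) datasets."""
    est = SoftMRS(**params)
    est.fit(_features(N), _features(R))
    return est
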