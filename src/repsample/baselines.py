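"""Baseline weighters: uniform, propensity-score adjustment, kernel mean matching.

PSA fits a linear log-odds model for cohort membership on the pooled
cohorts and weights each biased-cohort row by the inverse propensity
(1 - pi) / pi, where pi is the modeled probability of belonging to the
non-representative cohort — representative-looking rows are upweighted.
A small ridge penalty stabilizes the fit under separation, and pi is
clipped away from {0, 1}.

KMM chooses weights beta over the biased cohort N so that its weighted
mean embedding in the RBF kernel's RKHS matches the reference cohort's:

    minimize  1/2 beta' K beta - kappa' beta
    s.t.      0 <= beta_i <= B,   |sum(beta) - n| <= n * eps

with K the kernel matrix over N and kappa_i = (n/m) * sum_j k(n_i, r_j).
The quadratic program is solved through an injected solver callable so
the module can be exercised against a reference dense solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize
from sklearn.linear_model import LogisticRegression

from .base import BaseWeighter
from .errors import SolverError
from .mmd import KernelSpec, joint_zscore, rbf_matrix, sigma_heuristic

PI_CLIP = 1e-6


def _features(ds):
    return ds.features if hasattr(ds, "features") else np.asarray(ds, dtype=float)


class UniformWeights(BaseWeighter):
    """Naive baseline: every biased-cohort row gets weight 1."""

    def fit(self, X, X_reference=None):
        X = np.asarray(X, dtype=float)
        self.weights_ = np.ones(X.shape[0])
        return self


class PSAWeights(BaseWeighter):
    """Inverse-propensity weighting via ridge-penalized logistic regression."""

    def __init__(self, C=1.0, max_iter=1000, random_state=None):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, X_reference):
        X, R = self._validate_pair(X, X_reference)
        # standardize jointly only for optimizer conditioning
        R_s, X_s = joint_zscore(R, X)
        Z = np.vstack([R_s, X_s])
        y = np.concatenate([np.zeros(len(R), dtype=int), np.ones(len(X), dtype=int)])
        clf = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        )
        clf.fit(Z, y)
        col = list(clf.classes_).index(1)
        pi = clf.predict_proba(X_s)[:, col]
        if np.any(pi <= PI_CLIP) or np.any(pi >= 1 - PI_CLIP):
            warnings.warn(
                "propensity scores at the clipping bound; weights were clipped",
                RuntimeWarning,
                stacklevel=2,
            )
        pi = np.clip(pi, PI_CLIP, 1 - PI_CLIP)
        self.propensity_ = pi
        self.model_ = clf
        self.weights_ = inverse_propensity(pi)
        return self


def inverse_propensity(pi):
    """The PSA weight (1 - pi) / pi."""
    pi = np.asarray(pi, dtype=float)
    return (1.0 - pi) / pi


@dataclass
class KMMProblem:
    """Assembled KMM quadratic program (kept for diagnostics/testing)."""

    K: np.ndarray
    kappa: np.ndarray
    B: float
    eps: float

    def __post_init__(self):
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise SolverError("kernel matrix is not symmetric")
        if self.B <= 0 or self.eps < 0:
            raise SolverError("need B > 0 and eps >= 0")

    @property
    def n(self) -> int:
        return len(self.kappa)

    def objective(self, beta) -> float:
        beta = np.asarray(beta, dtype=float)
        return float(0.5 * beta @ self.K @ beta - self.kappa @ beta)


def solve_qp_trust_constr(problem: KMMProblem) -> np.ndarray:
    """Reference QP solver: scipy trust-constr with exact gradient/Hessian."""
    n = problem.n
    K, kappa = problem.K, problem.kappa
    constraint = LinearConstraint(
        np.ones((1, n)), n * (1.0 - problem.eps), n * (1.0 + problem.eps)
    )
    x0 = np.full(n, min(1.0, problem.B))
    res = minimize(
        problem.objective,
        x0,
        jac=lambda b: K @ b - kappa,
        hess=lambda b: K,
        bounds=[(0.0, problem.B)] * n,
        constraints=[constraint],
        method="trust-constr",
        options={"gtol": 1e-8, "xtol": 1e-10, "maxiter": 500},
    )
    if res.x is None or not np.all(np.isfinite(res.x)):
        raise SolverError(f"QP solver failed: {res.message}")
    beta = np.clip(res.x, 0.0, problem.B)
    total = beta.sum()
    if abs(total - n) > n * problem.eps + 1e-6:
        raise SolverError(
            f"solution violates the sum constraint: sum={total:.6f}, n={n}, eps={problem.eps}"
        )
    return beta


def build_kmm_problem(R, N, kernel=None, B=1000.0, eps=None, ridge=1e-8) -> KMMProblem:
    Xr, Xn = _features(R), _features(N)
    Xr_s, Xn_s = joint_zscore(Xr, Xn)
    if kernel is None:
        sigma = sigma_heuristic(Xr_s, Xn_s)
    elif isinstance(kernel, KernelSpec):
        sigma = kernel.sigma
    else:
        sigma = float(kernel)
    n, m = len(Xn_s), len(Xr_s)
    if eps is None:
        eps = (np.sqrt(n) - 1.0) / np.sqrt(n)
    K = rbf_matrix(Xn_s, Xn_s, sigma) + ridge * np.eye(n)
    kappa = (n / m) * rbf_matrix(Xn_s, Xr_s, sigma).sum(axis=1)
    return KMMProblem(K=K, kappa=kappa, B=float(B), eps=float(eps))


class KMMWeights(BaseWeighter):
    """Kernel-mean-matching weighter.

    Parameters
    ----------
    kernel : KernelSpec, float or None
        Bandwidth; None applies the aggregated-sample mean-distance
        heuristic on jointly standardized features.
    B : float
        Box bound on individual weights.
    eps : float or None
        Sum-constraint slack; None uses (sqrt(n) - 1) / sqrt(n).
    solver : callable or None
        ``solver(KMMProblem) -> beta``; None uses the scipy solver.
    """

    def __init__(self, kernel=None, B=1000.0, eps=None, solver=None):
        self.kernel = kernel
        self.B = B
        self.eps = eps
        self.solver = solver

    def fit(self, X, X_reference):
        X, R = self._validate_pair(X, X_reference)
        problem = build_kmm_problem(R, X, kernel=self.kernel, B=self.B, eps=self.eps)
        solver = self.solver if self.solver is not None else solve_qp_trust_constr
        self.problem_ = problem
        self.weights_ = np.asarray(solver(problem), dtype=float)
        return self


def uniform_weights(N) -> np.ndarray:
    return UniformWeights().fit_weights(_features(N), None)


def psa_weights(R, N, seed=None) -> np.ndarray:
    return PSAWeights(random_state=seed).fit_weights(_features(N), _features(R))


def kmm_weights(R, N, kernel=None, B=1000.0, eps=None, solver=None) -> np.ndarray:
    est = KMMWeights(kernel=kernel, B=B, eps=eps, solver=solver)
    return est.fit_weights(_features(N), _features(R))
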