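"""Kernel/MMD unit and property tests, checked against double-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repsample import (
    KernelSpec,
    WeightedMMDScorer,
    joint_zscore,
    mmd,
    rbf,
    sigma_heuristic,
    weighted_mmd,
)
from repsample.errors import DegenerateBandwidthError, DegenerateWeightsError


def mmd_loop(X, Y, sigma):
    """Literal double-loop V-statistic oracle."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    m, n = len(X), len(Y)
    k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
    t1 = sum(k(X[i], X[j]) for i in range(m) for j in range(m)) / m**2
    t2 = sum(k(X[i], Y[j]) for i in range(m) for j in range(n)) / (m * n)
    t3 = sum(k(Y[i], Y[j]) for i in range(n) for j in range(n)) / n**2
    return np.sqrt(max(t1 - 2 * t2 + t3, 0.0))


def weighted_mmd_loop(X, Y, w, sigma):
    """Double-loop oracle with Y's mean embedding weighted."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    m, n = len(X), len(Y)
    w = np.asarray(w, float) / np.sum(w)
    k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
    t1 = sum(k(X[i], X[j]) for i in range(m) for j in range(m)) / m**2
    t2 = sum(w[j] * k(X[i], Y[j]) for i in range(m) for j in range(n)) / m
    t3 = sum(w[i] * w[j] * k(Y[i], Y[j]) for i in range(n) for j in range(n))
    return np.sqrt(max(t1 - 2 * t2 + t3, 0.0))


class TestSigmaHeuristic:
    @pytest.mark.parametrize(
        "points,expected",
        [([[0.0], [2.0]], 2.0), ([[0.0], [1.0], [2.0]], 4.0 / 3.0)],
    )
    def test_hand_enumerated_pair_means(self, points, expected):
        assert sigma_heuristic(np.array(points)) == pytest.approx(expected)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateBandwidthError):
            sigma_heuristic(np.array([[5.0], [5.0]]))

    def test_pools_both_samples(self):
        # pooled {0, 2}: single pair, distance 2
        assert sigma_heuristic(np.array([[0.0]]), np.array([[2.0]])) == 2.0


class TestRBF:
    def test_zero_distance_is_one(self):
        assert rbf([1.0, 2.0], [1.0, 2.0], sigma=3.0) == 1.0

    def test_distance_sigma_sqrt2_is_inv_e(self):
        sigma = 0.7
        x, y = np.zeros(2), np.array([sigma * np.sqrt(2), 0.0])
        assert rbf(x, y, sigma) == pytest.approx(np.exp(-1.0))

    def test_direct_evaluation(self):
        assert rbf([0.0], [2.0], 1.0) == pytest.approx(np.exp(-2.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf([0.0], [0.0, 1.0], 1.0)


class TestMMD:
    def test_identical_multisets_zero(self, rng):
        X = rng.normal(size=(7, 2))
        assert mmd(X, X.copy(), 1.0).value <= 1e-12

    def test_two_point_hand_value(self):
        got = mmd(np.array([[0.0]]), np.array([[2.0]]), 1.0).value
        assert got == pytest.approx(np.sqrt(2 - 2 * np.exp(-2.0)), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        X, Y = rng.normal(size=(12, 3)), rng.normal(size=(9, 3))
        sigma = sigma_heuristic(X, Y)
        assert mmd(X, Y, sigma).value == pytest.approx(mmd_loop(X, Y, sigma), abs=1e-10)

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(6, 2)), rng.normal(size=(8, 2))
        assert mmd(X, Y, 1.3).value == pytest.approx(mmd(Y, X, 1.3).value, abs=1e-12)

    def test_kernelspec_accepted(self, rng):
        X, Y = rng.normal(size=(4, 2)), rng.normal(size=(5, 2))
        spec = KernelSpec(sigma=2.0, rule="fixed")
        out = mmd(X, Y, spec)
        assert out.sigma_used == 2.0 and out.value >= 0


class TestWeightedMMD:
    def test_uniform_weights_reduce_to_unweighted(self, rng):
        X, Y = rng.normal(size=(8, 3)), rng.normal(size=(10, 3))
        w = np.full(10, 3.7)
        assert weighted_mmd(X, Y, w, 1.1).value == pytest.approx(
            mmd(X, Y, 1.1).value, abs=1e-12
        )

    def test_zero_weight_rows_equal_removal(self, rng):
        X, Y = rng.normal(size=(6, 2)), rng.normal(size=(9, 2))
        w = np.ones(9)
        w[[2, 5]] = 0.0
        kept = np.delete(np.arange(9), [2, 5])
        assert weighted_mmd(X, Y, w, 0.9).value == pytest.approx(
            mmd(X, Y[kept], 0.9).value, abs=1e-12
        )

    def test_matches_weighted_double_loop(self, rng):
        X, Y = rng.normal(size=(7, 2)), rng.normal(size=(11, 2))
        w = rng.uniform(0.1, 2.0, size=11)
        assert weighted_mmd(X, Y, w, 1.4).value == pytest.approx(
            weighted_mmd_loop(X, Y, w, 1.4), abs=1e-10
        )

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_weight_rescaling(self, scale):
        rng = np.random.default_rng(7)
        X, Y = rng.normal(size=(5, 2)), rng.normal(size=(6, 2))
        w = rng.uniform(0.5, 1.5, size=6)
        a = weighted_mmd(X, Y, w, 1.0).value
        b = weighted_mmd(X, Y, w * scale, 1.0).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_all_zero_weights_rejected(self, rng):
        X, Y = rng.normal(size=(3, 1)), rng.normal(size=(4, 1))
        with pytest.raises(DegenerateWeightsError):
            weighted_mmd(X, Y, np.zeros(4), 1.0)

    def test_true_density_ratio_weights_drive_mmd_to_zero(self):
        # discrete toy: Y over-represents the point 1 by 3:1; importance
        # weights equal to the density ratio restore X's embedding
        X = np.array([[0.0]] * 5 + [[1.0]] * 5)
        Y = np.array([[0.0]] * 3 + [[1.0]] * 9)
        w = np.array([5 / 3] * 3 + [5 / 9] * 9)
        assert weighted_mmd(X, Y, w, 1.0).value <= 1e-12

    def test_scorer_agrees_with_weighted_mmd(self, rng):
        X, Y = rng.normal(size=(9, 3)), rng.normal(size=(12, 3))
        scorer = WeightedMMDScorer(X, Y, sigma=1.2)
        for _ in range(3):
            w = rng.uniform(0.2, 2.0, size=12)
            assert scorer(w) == pytest.approx(
                weighted_mmd(X, Y, w, 1.2).value, abs=1e-12
            )


def test_joint_zscore_pools_both_matrices(rng):
    X, Y = rng.normal(2.0, 3.0, size=(20, 2)), rng.normal(-1.0, 0.5, size=(30, 2))
    Xs, Ys = joint_zscore(X, Y)
    Z = np.vstack([Xs, Ys])
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)
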