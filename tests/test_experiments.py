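"""Orchestration-layer tests: trajectories, comparison harness, downstream demos."""

import numpy as np
import pytest
from scipy.stats import kstest

from repsample import (
    PopulationSpec,
    export_ecdf_comparison,
    generate_population,
    run_comparison,
    run_trajectory,
    weighted_logistic_lrt,
)
from repsample.baselines import UniformWeights
from repsample.errors import ConfigError, MetricError
from repsample.synthetic import inject_class_ratio_bias


@pytest.fixture(scope="module")
def small_population():
    return generate_population(PopulationSpec(n=400, seed=21))


class TestRunTrajectory:
    def test_structure_and_monitoring(self, small_population):
        pop = small_population
        rng = np.random.default_rng(0)
        idx = rng.permutation(pop.n)
        R, Nfull = pop.take(np.sort(idx[:200])), pop.take(np.sort(idx[200:]))
        N, _ = inject_class_ratio_bias(Nfull, 0, 0.3, seed=1)
        runs = run_trajectory(R, N, repeats=2, seed=3, drop_count=10, delta=0.02,
                              min_active=N.n - 40)
        assert len(runs) == 2
        for run in runs:
            recs = run["records"]
            iters = [r.iteration for r in recs]
            assert iters == sorted(iters)
            sizes = [r.active_n for r in recs]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))
            assert all(r.mmd is not None and r.mmd >= 0 for r in recs)
            assert all(r.relative_bias is not None for r in recs)

    def test_null_auroc_stays_near_half(self, dataset_factory):
        rng = np.random.default_rng(11)
        R = dataset_factory(rng.normal(size=(150, 3)))
        N = dataset_factory(rng.normal(size=(150, 3)))
        runs = run_trajectory(R, N, repeats=2, seed=0, drop_count=20,
                              min_active=90, compute_mmd=False)
        aurocs = [r.auroc for run in runs for r in run["records"]]
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.06)


class TestRunComparison:
    def test_record_bookkeeping(self, small_population):
        methods = {"uniform": lambda seed: UniformWeights()}
        report = run_comparison({"pop": small_population}, methods, trials=3,
                                seed=1, subsample=0)
        assert len(report.records) == 3
        df = report.frame()
        assert df["method"].unique().tolist() == ["uniform"]
        assert df["auroc"].between(0, 1).all()

    def test_duplicated_method_ties_are_averaged(self, small_population):
        methods = {
            "a": lambda seed: UniformWeights(),
            "b": lambda seed: UniformWeights(),
        }
        report = run_comparison({"pop": small_population}, methods, trials=2,
                                seed=2, subsample=0)
        table = report.mean_table("auroc")
        assert table.loc["a", "pop"] == table.loc["b", "pop"]
        ranks = report.ranks("auroc", higher_is_better=True)
        assert ranks["a"] == ranks["b"] == 1.5

    def test_population_without_target_rejected(self, dataset_factory, rng):
        ds = dataset_factory(rng.normal(size=(40, 2)))
        with pytest.raises(ConfigError):
            run_comparison({"x": ds}, {"uniform": lambda s: UniformWeights()},
                           trials=1, seed=0)

    def test_full_determinism(self, small_population):
        methods = {"uniform": lambda seed: UniformWeights()}
        a = run_comparison({"pop": small_population}, methods, trials=2, seed=9,
                           subsample=0).frame()
        b = run_comparison({"pop": small_population}, methods, trials=2, seed=9,
                           subsample=0).frame()
        assert a.equals(b)


class TestWeightedLogisticLRT:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=500)
            y = (rng.random(500) < 0.5).astype(float)
            pvals.append(weighted_logistic_lrt(x, y)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.filterwarnings("ignore:Perfect separation")
    def test_perfect_association_near_zero_p(self):
        x = np.r_[np.zeros(100), np.ones(100)]
        _, p = weighted_logistic_lrt(x, x.copy())
        assert p < 1e-6

    def test_row_duplication_with_halved_weights_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        c1, p1 = weighted_logistic_lrt(x, y)
        c2, p2 = weighted_logistic_lrt(np.r_[x, x], np.r_[y, y], np.full(400, 0.5))
        assert c1 == pytest.approx(c2, abs=1e-8)
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(MetricError):
            weighted_logistic_lrt(np.arange(5.0), np.ones(5))


class TestExportECDF:
    def test_uniform_weights_standard_steps(self):
        out = export_ecdf_comparison({"s": np.array([3.0, 1.0, 2.0])})
        np.testing.assert_allclose(out["x"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out["s"], [1 / 3, 2 / 3, 1.0])

    def test_zero_weight_rows_carry_no_mass(self):
        out = export_ecdf_comparison({"s": (np.array([1.0, 2.0]), np.array([1.0, 0.0]))})
        np.testing.assert_allclose(out["s"], [1.0, 1.0])

    def test_hand_built_weighted_series(self):
        out = export_ecdf_comparison(
            {"s": (np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 1.0]))}
        )
        np.testing.assert_allclose(out["s"], [0.25, 0.75, 1.0])

    def test_multiple_series_share_support(self):
        out = export_ecdf_comparison({"a": np.array([0.0]), "b": np.array([1.0])})
        assert out["x"].tolist() == [0.0, 1.0]
        np.testing.assert_allclose(out["a"], [1.0, 1.0])
        np.testing.assert_allclose(out["b"], [0.0, 1.0])
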