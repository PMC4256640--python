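"""Generator contracts: lattices, GMRF draws, covariates, counts, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wardmap.graph import build_mrf_precision
from wardmap.synthetic import (
    SyntheticTruth,
    default_scenario,
    make_lattice,
    recovery_experiment,
    simulate_counts,
    simulate_covariates,
    simulate_spatial_effect,
)


class TestMakeLattice:
    def test_2x2_rook(self):
        g = make_lattice(2, 2, "rook")
        assert g.n_nodes == 4 and g.n_edges == 4

    def test_2x2_queen(self):
        g = make_lattice(2, 2, "queen")
        assert g.n_nodes == 4 and g.n_edges == 6

    def test_study_scale_rook_lattice(self):
        g = make_lattice(15, 7, "rook")
        assert g.n_nodes == 105
        assert g.n_edges == 15 * 6 + 7 * 14  # 188

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_lattice(2, 2, "hexagon")


class TestSimulateSpatialEffect:
    def test_draws_sum_to_zero(self, rng):
        mrf = build_mrf_precision(make_lattice(5, 5))
        for _ in range(20):
            f = simulate_spatial_effect(mrf, 0.5, rng)
            assert abs(f.sum()) < 1e-10

    def test_quadratic_form_expectation_is_tau2_times_rank(self, rng):
        # E[f' Q f] = tau2 * rank(Q) = sum over edges of E[(f_r - f_s)^2]
        mrf = build_mrf_precision(make_lattice(4, 4))
        tau2 = 0.5
        Q = mrf.dense()
        quads = []
        for _ in range(10_000):
            f = simulate_spatial_effect(mrf, tau2, rng)
            quads.append(f @ (Q @ f))
        assert np.mean(quads) == pytest.approx(tau2 * mrf.rank, rel=0.05)

    def test_small_tau2_shrinks_to_zero(self, rng):
        mrf = build_mrf_precision(make_lattice(3, 3))
        f = simulate_spatial_effect(mrf, 1e-12, rng)
        assert np.abs(f).max() < 1e-5

    def test_nonpositive_tau2_rejected(self, rng):
        mrf = build_mrf_precision(make_lattice(2, 2))
        with pytest.raises(ValueError):
            simulate_spatial_effect(mrf, 0.0, rng)

    def test_marginals_are_gaussian(self, rng):
        # one ward's effect across replicates ~ N(0, tau2 * pinv(Q)_ii)
        mrf = build_mrf_precision(make_lattice(3, 3))
        tau2 = 0.4
        var = tau2 * np.diag(np.linalg.pinv(mrf.dense()))
        draws = np.array([simulate_spatial_effect(mrf, tau2, rng) for _ in range(500)])
        p = stats.kstest(draws[:, 4], "norm", args=(0.0, np.sqrt(var[4]))).pvalue
        assert p > 0.01


def _neighbour_corr(graph, x):
    pairs = graph.edge_index_pairs()
    return float(np.corrcoef(x[pairs[:, 0]], x[pairs[:, 1]])[0, 1])


class TestSimulateCovariates:
    def test_standardization_contract(self, rng):
        g = make_lattice(6, 6)
        df = simulate_covariates(g, 3, 0.5, rng)
        np.testing.assert_allclose(df.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(df.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_no_mixing_gives_uncorrelated_neighbours(self, rng):
        g = make_lattice(6, 6)
        corrs = [
            _neighbour_corr(g, simulate_covariates(g, 1, 0.0, rng)["x1"].to_numpy())
            for _ in range(100)
        ]
        assert abs(np.mean(corrs)) < 0.05

    def test_full_mixing_on_path_graph_is_smooth(self, rng):
        g = make_lattice(1, 50)  # path graph
        corrs = [
            _neighbour_corr(g, simulate_covariates(g, 1, 1.0, rng)["x1"].to_numpy())
            for _ in range(30)
        ]
        assert np.mean(corrs) > 0.5

    def test_correlation_mix_induces_cross_correlation(self, rng):
        g = make_lattice(10, 10)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        cors = []
        for _ in range(30):
            df = simulate_covariates(g, 2, 0.3, rng, correlation=R)
            cors.append(np.corrcoef(df["x1"], df["x2"])[0, 1])
        assert np.mean(cors) == pytest.approx(0.5, abs=0.1)


class TestSimulateCounts:
    def test_null_truth_gives_unit_rate_per_1000(self, rng):
        n = 10_000
        ids = [f"w{i}" for i in range(n)]
        truth = SyntheticTruth({}, np.zeros(n), 1.0, 0.0, np.full(n, 1000))
        ds = simulate_counts(truth, pd.DataFrame(index=ids), "per_1000_population", rng)
        assert ds.counts.mean() == pytest.approx(1.0, rel=0.05)

    def test_doubling_population_doubles_expected_count(self, rng):
        n = 5000
        ids = [f"w{i}" for i in range(n)]
        t1 = SyntheticTruth({}, np.zeros(n), 1.0, 1.0, np.full(n, 1000))
        t2 = SyntheticTruth({}, np.zeros(n), 1.0, 1.0, np.full(n, 2000))
        df = pd.DataFrame(index=ids)
        m1 = simulate_counts(t1, df, "per_1000_population", rng).counts.mean()
        m2 = simulate_counts(t2, df, "per_1000_population", rng).counts.mean()
        assert m2 / m1 == pytest.approx(2.0, rel=0.1)

    def test_seeded_run_reproducible(self):
        g, cov, truth = default_scenario(np.random.default_rng(5), rows=4, cols=4)
        a = simulate_counts(truth, cov, "per_1000_population", np.random.default_rng(9))
        b = simulate_counts(truth, cov, "per_1000_population", np.random.default_rng(9))
        assert a == b

    def test_overflowing_rate_rejected(self, rng):
        truth = SyntheticTruth({}, np.zeros(2), 1.0, 60.0, np.full(2, 1000))
        with pytest.raises(ValueError, match="smaller truth"):
            simulate_counts(truth, pd.DataFrame(index=["a", "b"]), "none", rng)


class TestDefaultScenario:
    def test_scale_and_validity(self):
        g, cov, truth = default_scenario(np.random.default_rng(0))
        assert g.n_nodes == 105
        assert list(cov.columns) == ["nox", "so2", "pm", "ben", "over50_pct", "imd"]
        assert (cov[["nox", "so2", "pm", "ben", "imd"]].to_numpy() >= 0).all()
        assert cov["over50_pct"].between(0, 100).all()
        assert truth.populations.min() >= 2000 - 1

    def test_populations_log_uniform(self):
        pops = []
        for s in range(10):
            _, _, truth = default_scenario(np.random.default_rng(s))
            pops.extend(np.log(truth.populations))
        p = stats.kstest(
            pops, stats.uniform(loc=np.log(2000), scale=np.log(10)).cdf
        ).pvalue
        assert p > 0.01


class TestRecoveryExperiment:
    def test_smoke_run_reports_schema_and_seeds(self):
        rep = recovery_experiment(
            2, seed=9, rows=4, cols=4,
            mcmc_settings={"n_iter": 400, "burn_in": 100, "thin": 3},
        )
        assert rep["n_replicates"] == 2
        assert len(rep["data_seeds"]) == 2 and len(rep["chain_seeds"]) == 2
        for nm, entry in rep["fixed_effects"].items():
            assert {"truth", "bias", "rmse", "coverage_95"} <= set(entry)
        assert len(rep["spatial_correlation"]["per_replicate"]) == 2

    def test_deterministic_given_seed(self):
        kw = dict(rows=4, cols=4, mcmc_settings={"n_iter": 300, "burn_in": 100, "thin": 2})
        a = recovery_experiment(1, seed=3, **kw)
        b = recovery_experiment(1, seed=3, **kw)
        assert a == b

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            recovery_experiment(0, seed=1)
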