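"""IWLS working quantities, block updates, variance Gibbs steps, full chains."""

import numpy as np
import pytest

from wardmap.io import WardDataset, WardRecord
from wardmap.model import ModelSpec, build_design
from wardmap.sampler import (
    MCMCConfig,
    center_effect,
    iwls_proposal,
    iwls_working_quantities,
    run_mcmc,
    sample_block,
    sample_variance,
)


def _poisson_dataset(n, rng, mean=20.0, covariates=()):
    recs = []
    for i in range(n):
        recs.append(
            WardRecord(
                f"w{i}",
                int(rng.poisson(mean)),
                1000,
                {c: float(rng.normal()) for c in covariates},
            )
        )
    return WardDataset(tuple(recs))


class TestIWLSWorkingQuantities:
    def test_zero_residual_gives_z_equal_eta(self):
        eta = np.array([0.1, -0.4, 1.2])
        mu = np.exp(eta)
        z, w = iwls_working_quantities(mu, eta, np.zeros(3))
        np.testing.assert_allclose(z, eta)
        np.testing.assert_allclose(w, mu)

    def test_direct_evaluation_at_zero(self):
        z, w = iwls_working_quantities([0.0], [0.0], [0.0])
        np.testing.assert_array_equal(z, [-1.0])
        np.testing.assert_array_equal(w, [1.0])

    def test_matches_elementwise_oracle(self, rng):
        n = 25
        y = rng.poisson(5.0, n).astype(float)
        eta = rng.normal(0, 1, n)
        offset = rng.normal(0, 0.3, n)
        z, w = iwls_working_quantities(y, eta, offset)
        for i in range(n):
            mu_i = np.exp(eta[i] + offset[i])
            assert abs(w[i] - mu_i) < 1e-12
            assert abs(z[i] - (eta[i] + (y[i] - mu_i) / mu_i)) < 1e-12

    def test_overflow_guard_keeps_weights_finite(self):
        z, w = iwls_working_quantities([1.0], [100.0], [0.0])
        assert np.isfinite(w).all() and np.isfinite(z).all()


class TestIWLSProposal:
    def test_infinite_tau2_limit_drops_shrinkage(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = rng.poisson(5.0, n).astype(float)
        eta = X @ np.array([1.0, 0.2])
        pen = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, m_pen, L_pen = iwls_proposal(y, eta, np.zeros(n), X, np.array([1.0, 0.2]), pen / 1e12)
        _, m_flat, L_flat = iwls_proposal(
            y, eta, np.zeros(n), X, np.array([1.0, 0.2]), np.zeros((2, 2))
        )
        np.testing.assert_allclose(m_pen, m_flat, atol=1e-8)
        np.testing.assert_allclose(L_pen @ L_pen.T, L_flat @ L_flat.T, atol=1e-8)

    def test_collinear_design_raises_with_advice(self, rng):
        n = 20
        x = rng.normal(0, 1, n)
        X = np.column_stack([x, x])  # exactly collinear
        y = rng.poisson(3.0, n).astype(float)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            iwls_proposal(y, X @ np.zeros(2), np.zeros(n), X, np.zeros(2), np.zeros((2, 2)))


class TestSampleBlock:
    def test_gaussian_likelihood_always_accepts(self, rng):
        # proposal equals the full conditional => MH ratio 1
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = X @ np.array([0.5, -0.2]) + rng.normal(0, 0.5, n)
        coef = np.zeros(2)
        eta = X @ coef
        accepted = []
        for _ in range(50):
            coef, eta, ok = sample_block(
                y, eta, np.zeros(n), X, coef, np.zeros((2, 2)), 1.0, rng,
                likelihood="gaussian", gaussian_sigma2=0.25,
            )
            accepted.append(ok)
        assert all(accepted)


class TestSampleVariance:
    def test_inverse_gamma_mean_matches_formula(self, rng):
        # shape 3, rate 4 => mean 4 / (3 - 1) = 2
        draws = [
            sample_variance(np.zeros(2), np.zeros((2, 2)), 3.0, 4.0, rng, rank=0)
            for _ in range(100_000)
        ]
        assert np.mean(draws) == pytest.approx(2.0, rel=0.02)

    def test_shape_uses_rank_and_quadratic_form(self, rng):
        # penalty of rank 3 with coef'K coef = 2 targets IG(a + 1.5, b + 1)
        pen = np.diag([1.0, 1.0, 2.0, 0.0])
        coef = np.array([1.0, 0.0, np.sqrt(0.5), 5.0])  # quad form = 1 + 1 = 2
        quad = coef @ pen @ coef
        assert quad == pytest.approx(2.0)
        a, b = 0.001, 0.001
        seed = 99
        draw = sample_variance(coef, pen, a, b, np.random.default_rng(seed), rank=3)
        expected = (b + quad / 2) / np.random.default_rng(seed).gamma(a + 1.5)
        assert draw == pytest.approx(expected, rel=1e-12)

    def test_nullspace_coef_leaves_rate_at_prior(self, rng):
        from wardmap.smoothers import rw_penalty

        pen = rw_penalty(6, 2)
        coef = 2.0 + 0.5 * np.arange(6)  # in the RW2 nullspace
        seed = 7
        draw = sample_variance(coef, pen, 1.0, 3.0, np.random.default_rng(seed), rank=4)
        expected = 3.0 / np.random.default_rng(seed).gamma(1.0 + 2.0)
        assert draw == pytest.approx(expected, rel=1e-10)


class TestCenterEffect:
    def test_single_group(self):
        c, consts = center_effect([1.0, 2.0, 3.0], [np.arange(3)])
        np.testing.assert_allclose(c, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(consts, [2.0])

    def test_idempotent_on_centered_vector(self):
        c, consts = center_effect([-1.0, 0.0, 1.0], [np.arange(3)])
        np.testing.assert_allclose(c, [-1.0, 0.0, 1.0])
        assert consts[0] == 0.0

    def test_two_components(self):
        c, consts = center_effect([1.0, 3.0, 5.0], [np.array([0, 1]), np.array([2])])
        np.testing.assert_allclose(c, [-1.0, 1.0, 0.0])
        np.testing.assert_allclose(consts, [2.0, 5.0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            center_effect([1.0], [np.array([], dtype=int)])


class TestRunMCMC:
    def test_intercept_only_posterior_mode_near_log_mean(self, rng):
        ds = _poisson_dataset(50, rng, mean=100.0)
        fit = build_design(ds, ModelSpec(offset_mode="none"))
        chains = run_mcmc(fit, MCMCConfig(seed=4, n_iter=3000, burn_in=500, thin=5))
        post_mean = chains.draws["intercept"].mean()
        assert abs(post_mean - np.log(ds.counts.mean())) < 0.05

    def test_same_seed_bitwise_identical(self, rng):
        from wardmap.synthetic import make_lattice

        ds = _poisson_dataset(16, rng, covariates=("u",))
        g = make_lattice(4, 4)
        ds = WardDataset(
            tuple(
                WardRecord(g.node_ids[i], r.count, r.population, r.covariates)
                for i, r in enumerate(ds.records)
            )
        )
        spec = ModelSpec(fixed_terms=("u",), spatial=True, offset_mode="none")
        fit = build_design(ds, spec, g)
        cfg = MCMCConfig(seed=11, n_iter=400, burn_in=100, thin=2)
        a = run_mcmc(fit, cfg)
        b = run_mcmc(fit, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])
        c = run_mcmc(fit, MCMCConfig(seed=12, n_iter=400, burn_in=100, thin=2))
        assert not np.array_equal(a.draws["fixed"], c.draws["fixed"])

    def test_variance_draws_positive_and_spatial_draws_centered(self, rng):
        # disconnected graph: the centering constraint holds per component
        from wardmap.graph import WardGraph

        ids = ("a", "b", "c", "d", "e", "f")
        g = WardGraph(ids, (("a", "b"), ("b", "c"), ("d", "e"), ("e", "f")))
        recs = tuple(WardRecord(i, int(rng.poisson(20)), 1000, {}) for i in ids)
        fit = build_design(WardDataset(recs), ModelSpec(spatial=True, offset_mode="none"), g)
        chains = run_mcmc(fit, MCMCConfig(seed=2, n_iter=600, burn_in=100, thin=2))
        assert (chains.draws["tau2_spatial"] > 0).all()
        spat = chains.draws["spatial"]
        for comp in ([0, 1, 2], [3, 4, 5]):
            np.testing.assert_allclose(spat[:, comp].mean(axis=1), 0.0, atol=1e-12)

    def test_acceptance_rates_healthy_on_well_scaled_problem(self):
        from wardmap.graph import build_mrf_precision
        from wardmap.synthetic import (
            SyntheticTruth,
            make_lattice,
            simulate_counts,
            simulate_covariates,
            simulate_spatial_effect,
        )

        rng = np.random.default_rng(5)
        g = make_lattice(6, 6)
        cov = simulate_covariates(g, 2, 0.5, rng, names=["a", "b"])
        f = simulate_spatial_effect(build_mrf_precision(g), 0.1, rng)
        truth = SyntheticTruth(
            {"a": 0.2, "b": -0.1}, f, 0.1, np.log(30.0), np.full(36, 1000)
        )
        ds = simulate_counts(truth, cov, "per_1000_population", rng)
        fit = build_design(ds, ModelSpec(fixed_terms=("a", "b"), spatial=True), g)
        chains = run_mcmc(fit, MCMCConfig(seed=7, n_iter=2000, burn_in=500, thin=5))
        for name, rate in chains.acceptance_rates.items():
            assert 0.3 <= rate <= 1.0, (name, rate)

    def test_all_zero_counts_warns_but_runs(self):
        recs = tuple(WardRecord(f"w{i}", 0, 1000, {}) for i in range(10))
        fit = build_design(WardDataset(recs), ModelSpec(offset_mode="none"))
        with pytest.warns(RuntimeWarning, match="zero"):
            chains = run_mcmc(fit, MCMCConfig(seed=1, n_iter=300, burn_in=100, thin=1))
        assert np.isfinite(chains.draws["intercept"]).all()

    def test_smooth_term_chain_runs_and_centers(self, rng):
        n = 60
        recs = tuple(
            WardRecord(f"w{i}", int(rng.poisson(15)), 1000, {"u": float(i) / n})
            for i in range(n)
        )
        spec = ModelSpec(
            smooth_terms=(("u", {"n_inner_knots": 6, "degree": 3}),), offset_mode="none"
        )
        fit = build_design(WardDataset(recs), spec)
        chains = run_mcmc(fit, MCMCConfig(seed=3, n_iter=800, burn_in=200, thin=2))
        gam = chains.draws["smooth_u"]
        np.testing.assert_allclose(gam.mean(axis=1), 0.0, atol=1e-12)
        assert (chains.draws["tau2_smooth_u"] > 0).all()
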