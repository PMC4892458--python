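import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylosoc as ps
from conftest import pgls_inputs


def ols_oracle(y, x):
    """Hand-rolled ordinary least squares via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestGLS:
    def test_identity_correlation_equals_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(10, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = ps.gls_fit(y, x)
            expected = ols_oracle(y, x)
            np.testing.assert_allclose(
                fit.coefficients["mean"].to_numpy(), expected, atol=1e-10
            )

    def test_two_point_saturated_fit_flagged(self):
        est = ps.PhylogeneticGLS().fit(np.array([0.0, 1.0]), np.array([1.0, 3.0]))
        assert est.saturated_
        assert est.intercept_ == pytest.approx(1.0)
        assert est.coef_[0] == pytest.approx(2.0)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ps.gls_fit(np.arange(5.0), np.ones(5))

    def test_recovers_slope_and_mixing_on_tree_data(self):
        # moderate-size check; the heavier replication lives in acceptance
        hits = 0
        h_ok = 0
        for rep in range(20):
            _, _, corr, y, x = pgls_inputs(120, seed=100 + rep, sigma2_phylo=0.15,
                                           sigma2_resid=0.15)
            est = ps.PhylogeneticGLS().fit(x, y, corr=corr)
            se = est.se_[1]
            if abs(est.coef_[0] - (-0.4)) < 3 * se:
                hits += 1
            if abs(est.mixing_ - 0.5) < 0.25:
                h_ok += 1
        assert hits >= 18
        assert h_ok >= 14

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            ps.gls_fit(np.array([1.0, 2.0]), np.array([0.0, 1.0]), corr=bad)


class TestMixedMCMC:
    def test_determinism_bit_identical(self):
        _, _, corr, y, x = pgls_inputs(40, seed=7)
        cfg = ps.ChainConfig(n_iterations=3000, burn_in=500, thinning=5, seed=11)
        _, s1 = ps.mixed_mcmc(y, x, corr=corr, config=cfg)
        _, s2 = ps.mixed_mcmc(y, x, corr=corr, config=cfg)
        pd.testing.assert_frame_equal(s1, s2)

    def test_too_few_retained_samples_rejected(self):
        _, _, corr, y, x = pgls_inputs(20, seed=8)
        cfg = ps.ChainConfig(n_iterations=1000, burn_in=500, thinning=10, seed=0)
        with pytest.raises(ValueError, match="longer chain|retained"):
            ps.mixed_mcmc(y, x, corr=corr, config=cfg)

    def test_posterior_mean_matches_exact_integration_oracle(self):
        # independent oracle: 2-D numerical integration of the exact
        # marginal posterior over the two variance components at n=30
        from scipy.stats import invgamma

        tree, m, corr, y, x = pgls_inputs(30, seed=3000 - 1)
        R = corr.values
        n = len(y)
        X = np.column_stack([np.ones(n), x])
        tau2, a, b = 1e8, 1e-3, 1e-3

        def log_marg(s2u, s2e):
            V = s2u * R + s2e * np.eye(n) + tau2 * (X @ X.T)
            _, ld = np.linalg.slogdet(V)
            q = y @ np.linalg.solve(V, y)
            return (
                -0.5 * (ld + q)
                + invgamma.logpdf(s2u, a, scale=b)
                + invgamma.logpdf(s2e, a, scale=b)
            )

        def cond_beta(s2u, s2e):
            V = s2u * R + s2e * np.eye(n)
            A = X.T @ np.linalg.solve(V, X) + np.eye(2) / tau2
            return np.linalg.solve(A, X.T @ np.linalg.solve(V, y))

        grid = np.exp(np.linspace(np.log(1e-4), np.log(3.0), 80))
        lw = np.array([[log_marg(u, e) for e in grid] for u in grid])
        w = np.exp(lw - lw.max()) * np.outer(grid, grid)  # log-spaced quadrature
        w /= w.sum()
        exact = np.zeros(2)
        for i, u in enumerate(grid):
            for j, e in enumerate(grid):
                if w[i, j] > 1e-12:
                    exact += w[i, j] * cond_beta(u, e)

        cfg = ps.ChainConfig(n_iterations=60000, burn_in=10000, thinning=5, seed=5)
        _, samples = ps.mixed_mcmc(y, x, corr=corr, config=cfg)
        for k, name in enumerate(("intercept", "slope")):
            s = samples[name].to_numpy()
            mcse = s.std(ddof=1) / np.sqrt(ps.effective_sample_size(s))
            assert abs(s.mean() - exact[k]) < 4 * mcse + 2e-3

    def test_grouping_random_effect_recovers_slope(self):
        rng = np.random.default_rng(2)
        n = 160
        groups = np.repeat(["w", "a", "b", "m"], n // 4)
        eff = dict(zip("wabm", rng.normal(0, 0.5, 4)))
        x = rng.normal(size=n)
        y = 1.0 - 0.36 * x + np.array([eff[g] for g in groups]) + rng.normal(0, 0.3, n)
        cfg = ps.ChainConfig(n_iterations=6000, burn_in=1000, thinning=5, seed=3)
        fit, _ = ps.mixed_mcmc(y, x, groups=groups, config=cfg)
        row = fit.coefficients.loc["slope"]
        assert row["lower_95"] < -0.36 < row["upper_95"]
        assert fit.coefficients.loc["slope", "p"] < 0.01


class TestPMCMC:
    def test_all_negative_hits_floor(self):
        draws = -np.abs(np.random.default_rng(0).normal(size=500))
        assert ps.p_mcmc(draws) == pytest.approx(2 / 500)

    def test_symmetric_draws_near_one(self):
        draws = np.random.default_rng(1).standard_normal(10_000)
        assert ps.p_mcmc(draws) == pytest.approx(1.0, abs=0.05)

    def test_quarter_positive(self):
        assert ps.p_mcmc(np.array([-1.0, -1.0, -1.0, 1.0])) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ps.p_mcmc([])

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance_and_sign_antisymmetry(self, scale, seed):
        draws = np.random.default_rng(seed).normal(0.3, 1.0, size=300)
        p = ps.p_mcmc(draws)
        assert ps.p_mcmc(scale * draws) == p
        assert ps.p_mcmc(-draws) == p


class TestGeweke:
    def test_iid_chain_null(self):
        chain = np.random.default_rng(4).standard_normal(10_000)
        assert abs(ps.geweke_z(chain)) < 3

    def test_trend_detected(self):
        assert abs(ps.geweke_z(np.arange(10_000) / 1000.0 +
                               np.random.default_rng(5).normal(0, .1, 10_000))) > 3

    def test_location_invariance(self):
        chain = np.random.default_rng(6).standard_normal(2_000)
        assert ps.geweke_z(chain + 100.0) == pytest.approx(ps.geweke_z(chain))

    def test_degenerate_chain_errors(self):
        with pytest.raises(ValueError):
            ps.geweke_z(np.ones(1000))


class TestESS:
    def test_iid_chain(self):
        chain = np.random.default_rng(7).standard_normal(10_000)
        assert 8_000 <= ps.effective_sample_size(chain) <= 12_000

    def test_repeated_values_reduce_ess(self):
        base = np.random.default_rng(8).standard_normal(1_000)
        chain = np.repeat(base, 10)
        ess = ps.effective_sample_size(chain)
        assert 0.7 * 1_000 <= ess <= 1.3 * 1_000

    def test_constant_chain_errors(self):
        with pytest.raises(ValueError):
            ps.effective_sample_size(np.full(500, 2.0))


class TestSummarizePosterior:
    def test_toy_mean(self):
        df = pd.DataFrame({"slope": np.tile([1.0, 2.0, 3.0, 4.0], 25)})
        fit = ps.summarize_posterior(df, fixed=["slope"])
        assert fit.coefficients.loc["slope", "mean"] == pytest.approx(2.5)

    def test_normal_quantiles(self):
        draws = np.random.default_rng(9).standard_normal(100_000)
        fit = ps.summarize_posterior(pd.DataFrame({"slope": draws}), fixed=["slope"])
        assert fit.coefficients.loc["slope", "lower_95"] == pytest.approx(-1.96, abs=0.03)
        assert fit.coefficients.loc["slope", "upper_95"] == pytest.approx(1.96, abs=0.03)

    def test_one_sided_draws_floor_p(self):
        draws = np.abs(np.random.default_rng(10).standard_normal(400)) + 0.01
        fit = ps.summarize_posterior(pd.DataFrame({"slope": draws}), fixed=["slope"])
        assert fit.coefficients.loc["slope", "p"] == pytest.approx(2 / 400)

    def test_ess_cross_checked_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(11)
        # AR(1) chain with known strong autocorrelation
        n, phi = 5_000, 0.8
        chain = np.empty(n)
        chain[0] = rng.standard_normal()
        for i in range(1, n):
            chain[i] = phi * chain[i - 1] + rng.standard_normal()
        ours = ps.effective_sample_size(chain)
        theirs = float(arviz.ess(chain[None, :]))
        assert ours == pytest.approx(theirs, rel=0.3)
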