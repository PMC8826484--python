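"""Wright-Fisher engine, pool-sampling emulation, Ne fit, and ABC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempopool.wf import (
    EffectiveSizeGridModel,
    ExactMatchABC,
    SamplingScheme,
    WFConfig,
    deterministic_trajectory,
    sample_pools,
    simulate_frequencies,
    simulate_trajectory,
)


def drift_variance(f0, n, t):
    """Closed-form variance of the frequency after t generations of drift."""
    return f0 * (1 - f0) * (1 - (1 - 1 / (2 * n)) ** t)


class TestTrajectory:
    def test_absorbing_states_are_constant(self):
        for f0 in (0.0, 1.0):
            traj = simulate_trajectory(WFConfig(500, 200, f0=f0, seed=1))
            assert (traj == f0).all()

    def test_bounded_and_absorbing_mid_run(self):
        rng = np.random.default_rng(2)
        traj = simulate_trajectory(WFConfig(20, 500, f0=0.1), rng=rng)
        assert ((traj >= 0) & (traj <= 1)).all()
        hit = np.flatnonzero((traj == 0) | (traj == 1))
        if hit.size:
            assert (traj[hit[0] :] == traj[hit[0]]).all()

    def test_drift_variance_matches_closed_form(self):
        # same oracle as the published drift expectation
        rng = np.random.default_rng(3)
        n, t, reps, f0 = 1000, 100, 10_000, 0.5
        final = simulate_frequencies(np.full(reps, f0), n, t, rng=rng)
        expected = drift_variance(f0, n, t)
        sample_var = np.var(final - f0, ddof=1)
        se = expected * np.sqrt(2.0 / (reps - 1))  # SE of a variance estimate
        assert sample_var == pytest.approx(expected, abs=3 * se)

    def test_mean_frequency_conserved_without_selection(self):
        rng = np.random.default_rng(4)
        final = simulate_frequencies(np.full(20_000, 0.3), 200, 50, rng=rng)
        assert final.mean() == pytest.approx(0.3, abs=3 * final.std() / np.sqrt(20_000))

    def test_deterministic_selection_limit(self):
        # published MAP-style parameters drive the allele above 1/2 in 120 gens
        traj = deterministic_trajectory(0.0455, 0.0675, 120)
        assert traj[-1] > 0.5
        # logit increments are exactly log(1+s) under genic selection
        logit = np.log(traj / (1 - traj))
        np.testing.assert_allclose(np.diff(logit), np.log(1.0675), rtol=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WFConfig(0, 10)
        with pytest.raises(ValueError):
            WFConfig(10, 10, f0=1.5)
        with pytest.raises(ValueError):
            WFConfig(10, 10, s=-1.5)


class TestSamplePools:
    def test_lost_allele_observed_as_zero(self):
        scheme = SamplingScheme(np.array([20.0, 30.0]), np.array([40]))
        rng = np.random.default_rng(0)
        assert sample_pools(0.0, scheme, rng) == 0.0

    def test_deep_sampling_recovers_truth(self):
        scheme = SamplingScheme(np.array([5000.0]), np.array([100_000]))
        rng = np.random.default_rng(1)
        est = sample_pools(np.full(200, 0.37), scheme, rng)
        assert est.mean() == pytest.approx(0.37, abs=0.002)

    def test_variance_matches_compound_binomial(self):
        # Var = f(1-f) [ 1/(2ne) + (1 - 1/(2ne)) E[1/cov] ] for one pool
        ne, cov, f, reps = 10, 30, 0.5, 100_000
        scheme = SamplingScheme(np.array([float(ne)]), np.array([cov]))
        rng = np.random.default_rng(2)
        est = sample_pools(np.full(reps, f), scheme, rng)
        expected = f * (1 - f) * (1 / (2 * ne) + (1 - 1 / (2 * ne)) / cov)
        se = expected * np.sqrt(2.0 / (reps - 1))
        assert np.var(est, ddof=1) == pytest.approx(expected, abs=4 * se)


class TestEffectiveSizeGridModel:
    def _observed(self, seed, n_truth=8000, t=200, n_snps=3000):
        rng = np.random.default_rng(seed)
        f1 = rng.uniform(0.05, 0.95, n_snps)
        f2 = simulate_frequencies(f1, n_truth, t, rng=rng)
        scheme = SamplingScheme(np.array([40.0] * 4), rng.poisson(60, 500) + 1)
        obs_new = sample_pools(f2, scheme, rng)
        return f1, obs_new, scheme

    def test_single_value_grid_returns_it(self):
        f1, obs_new, scheme = self._observed(5)
        model = EffectiveSizeGridModel(f1, obs_new, scheme, generations=200)
        res = model.fit([4242], n_snps=500, seed=0)
        assert res.best_n == 4242
        assert "4242" in res.summary()

    def test_dispersion_monotone_in_time_and_population_size(self):
        rng = np.random.default_rng(6)
        f0 = np.full(4000, 0.5)
        short = np.abs(simulate_frequencies(f0, 2000, 50, rng=rng) - 0.5).mean()
        long = np.abs(simulate_frequencies(f0, 2000, 200, rng=rng) - 0.5).mean()
        assert long > short
        small = np.abs(simulate_frequencies(f0, 500, 100, rng=rng) - 0.5).mean()
        big = np.abs(simulate_frequencies(f0, 50_000, 100, rng=rng) - 0.5).mean()
        assert small > big

    def test_profile_decreases_in_population_size(self):
        f1, obs_new, scheme = self._observed(7)
        model = EffectiveSizeGridModel(f1, obs_new, scheme, generations=200)
        res = model.fit([500, 2000, 8000, 32_000], n_snps=2000, seed=1)
        assert (np.diff(res.profile) < 0).all()

    def test_rejects_disjoint_sites(self):
        scheme = SamplingScheme(np.array([40.0]), np.array([50]))
        with pytest.raises(ValueError):
            EffectiveSizeGridModel([np.nan], [np.nan], scheme, 10)


class TestExactMatchABC:
    def test_unconditional_acceptance_recovers_prior(self):
        # a zero-size sample matches any trajectory, so the posterior is the prior
        counts = pd.DataFrame({"year": [1975, 1979], "n": [0, 0], "k": [0, 0]})
        res = ExactMatchABC(counts).fit(n_accept=4000, seed=8, batch=4000)
        ks_s = stats.kstest(res.accepted_s, stats.uniform(0, 0.3).cdf)
        ks_f = stats.kstest(res.accepted_f0, stats.uniform(0, 0.2).cdf)
        assert ks_s.pvalue > 0.01 and ks_f.pvalue > 0.01

    def test_absent_allele_forces_rare_initial_frequency(self):
        counts = pd.DataFrame({"year": [1975], "n": [100], "k": [0]})
        res = ExactMatchABC(counts).fit(n_accept=3000, seed=9)
        assert np.quantile(res.accepted_f0, 0.9) < 0.05

    def test_flat_counts_disfavour_strong_selection(self):
        counts = pd.DataFrame(
            {"year": [1975, 1979, 1983], "n": [40, 40, 40], "k": [4, 4, 4]}
        )
        res = ExactMatchABC(counts).fit(n_accept=2000, seed=10)
        # posterior mass below s=0.05 must beat the prior's 1/6
        assert np.mean(res.accepted_s < 0.05) > 2 * (0.05 / 0.3)

    def test_literal_and_thinned_samplers_agree(self):
        # the envelope-thinned sampler draws from the same posterior as the
        # literal exact-count rejection sampler
        counts = pd.DataFrame({"year": [1975, 1977], "n": [5, 5], "k": [1, 2]})
        lit = ExactMatchABC(counts).fit(n_accept=2500, seed=11, method="literal")
        thin = ExactMatchABC(counts).fit(n_accept=2500, seed=12, method="thinned")
        for a, b in ((lit.accepted_s, thin.accepted_s), (lit.accepted_f0, thin.accepted_f0)):
            assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_map_and_ci_are_within_prior_support(self):
        counts = pd.DataFrame({"year": [1975, 1981], "n": [30, 30], "k": [2, 12]})
        res = ExactMatchABC(counts).fit(n_accept=1500, seed=13)
        assert 0.0 <= res.map_s <= 0.3 and 0.0 <= res.map_f0 <= 0.2
        assert res.ci_s[0] <= res.map_s or res.ci_s[0] <= res.ci_s[1]
        assert "MAP" in res.summary()

    def test_impossible_counts_abort_with_diagnostic(self):
        counts = pd.DataFrame({"year": [1975, 1976], "n": [50, 50], "k": [50, 0]})
        with pytest.raises(RuntimeError, match="acceptance rate"):
            ExactMatchABC(counts).fit(
                n_accept=100, seed=14, batch=100_000, max_simulations=400_000
            )

    def test_count_validation(self):
        with pytest.raises(ValueError):
            ExactMatchABC(pd.DataFrame({"year": [1975], "n": [10], "k": [11]}))
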