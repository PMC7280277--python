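import time

import numpy as np
import pytest
from scipy import stats

from conftest import make_design
from epibayes.model import CovariateGroup, GroupedDesign, Hyperparams, standardize, standardize_phenotype
from epibayes.sampler import (
    SamplerState,
    mixture_log_likelihoods,
    run_chain,
    sample_effect,
    sample_group_variance,
    sample_intercept,
    sample_pi,
    sample_residual_variance,
    sample_scaled_inv_chi2,
    select_mixture,
    selection_probabilities,
)
from oracles import batch_means_se, exact_slab_posterior, log_marginal_ratio_quadrature


def _fixed_state(design, sigma_eps_sq=1.0, sigma_g_sq=1.0):
    st = SamplerState.initial(design)
    st.sigma_eps_sq = sigma_eps_sq
    st.sigma_g_sq[:] = sigma_g_sq
    return st


class TestIntercept:
    def test_draws_match_stated_normal(self, rng):
        n = 100
        y = np.full(n, 2.0)
        design = GroupedDesign(
            y=standardize_phenotype(np.arange(n, dtype=float)),
            groups=[CovariateGroup("g", standardize(rng.normal(size=(n, 2))), (0.01,))],
        )
        draws = np.empty(10_000)
        for i in range(draws.size):
            st = _fixed_state(design)
            st.eps = y.copy()  # eps + mu_old has mean 2
            st.mu = 0.0
            draws[i] = sample_intercept(st, y, rng)
        assert abs(draws.mean() - 2.0) < 5 * 0.1 / np.sqrt(draws.size)
        assert abs(draws.std() - 0.1) < 0.005

    def test_residual_bookkeeping(self, rng):
        design, _, _ = make_design(seed=1)
        Z = design.full_matrix()
        st = _fixed_state(design)
        for _ in range(5):
            sample_intercept(st, design.y, rng)
            np.testing.assert_allclose(
                design.y - st.mu - Z @ st.theta, st.eps, atol=1e-8
            )


class TestMixtureSelection:
    def test_vanishing_slabs_reduce_to_prior(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        scores = mixture_log_likelihoods(
            zj_ty=3.0, zj_tz=50.0, sigma_eps_sq=1.0, sigma_g_sq=1e-300,
            C=(0.001, 0.01, 0.1), pi=pi,
        )
        np.testing.assert_allclose(selection_probabilities(scores), pi, atol=1e-10)

    def test_no_signal_favors_spike(self):
        scores = mixture_log_likelihoods(
            zj_ty=0.0, zj_tz=100.0, sigma_eps_sq=1.0, sigma_g_sq=1.0,
            C=(0.001, 0.01, 0.1), pi=np.full(4, 0.25),
        )
        assert np.argmax(scores) == 0  # slabs pay the determinant penalty

    @pytest.mark.parametrize("zj_ty", [0.0, 2.0, 15.0, -40.0])
    def test_matches_quadrature(self, zj_ty):
        """Slab-vs-spike score differences agree with numerically integrated
        marginal likelihoods on a toy single-covariate problem (N=50)."""
        zj_tz, s2, sg2 = 49.0, 0.8, 0.5
        C = (0.001, 0.01, 0.1)
        pi = np.full(4, 0.25)
        scores = mixture_log_likelihoods(zj_ty, zj_tz, s2, sg2, C, pi)
        for l, c in enumerate(C, start=1):
            expected = log_marginal_ratio_quadrature(zj_ty, zj_tz, s2, sg2 * c)
            assert scores[l] - scores[0] == pytest.approx(expected, abs=1e-6)

    def test_equal_scores_uniform(self, rng):
        counts = np.bincount(
            [select_mixture(np.zeros(4), rng) for _ in range(8000)], minlength=4
        )
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_dominant_score_always_selected(self, rng):
        scores = np.array([0.0, -1000.0, -1000.0, -1000.0])
        assert all(select_mixture(scores, rng) == 0 for _ in range(50))

    def test_probabilities_normalized(self, rng):
        for _ in range(1000):
            p = selection_probabilities(rng.normal(scale=30, size=rng.integers(2, 6)))
            assert abs(p.sum() - 1.0) < 1e-12

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            mixture_log_likelihoods(1.0, -1.0, 1.0, 1.0, (0.1,), (0.5, 0.5))
        with pytest.raises(ValueError):
            mixture_log_likelihoods(1.0, 10.0, -1.0, 1.0, (0.1,), (0.5, 0.5))


class TestEffectUpdate:
    def test_spike_restores_residual(self, rng):
        design, _, _ = make_design(seed=2)
        st = _fixed_state(design)
        st.pi_g[0] = np.array([1.0, 0.0, 0.0, 0.0])  # force the spike
        eps_before = st.eps.copy()
        sample_effect(3, st, design, rng)
        assert st.theta[3] == 0.0
        np.testing.assert_allclose(st.eps, eps_before, atol=0)

    def test_single_covariate_conjugate_mean(self, rng):
        n = 80
        r = np.random.default_rng(0)
        Z = standardize(r.normal(size=(n, 1)))
        y = standardize_phenotype(0.5 * Z[:, 0] + r.normal(size=n))
        design = GroupedDesign(y=y, groups=[CovariateGroup("g", Z, (1.0,))])
        st = _fixed_state(design, sigma_eps_sq=0.7, sigma_g_sq=0.5)
        st.pi_g[0] = np.array([0.0, 1.0])  # one slab forced
        draws = np.empty(20_000)
        for i in range(draws.size):
            sample_effect(0, st, design, rng)
            draws[i] = st.theta[0]
        ztz = float(Z[:, 0] @ Z[:, 0])
        zty = float(Z[:, 0] @ y)
        prec = ztz + 0.7 / 0.5
        expected_mean = zty / prec
        se = np.sqrt(0.7 / prec) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected_mean) < 3 * se

    def test_collinear_pair_sums_to_closed_form(self, rng):
        """Two identical columns: the posterior-mean sum equals the
        single-column closed form with doubled slab variance."""
        n = 100
        r = np.random.default_rng(5)
        z = standardize(r.normal(size=(n, 1)))[:, 0]
        Z = np.column_stack([z, z])
        y = standardize_phenotype(0.8 * z + r.normal(size=n))
        design = GroupedDesign(
            y=y, groups=[CovariateGroup("g", Z, (1.0,), col_ids=["a", "b"])]
        )
        st = _fixed_state(design, sigma_eps_sq=0.6, sigma_g_sq=0.4)
        st.pi_g[0] = np.array([0.0, 1.0])
        sums = np.empty(20_000)
        for i in range(sums.size):
            sample_effect(0, st, design, rng)
            sample_effect(1, st, design, rng)
            sums[i] = st.theta.sum()
        ztz = float(z @ z)
        expected = (z @ y) / (ztz + 0.6 / (2 * 0.4))
        assert abs(sums.mean() - expected) < 3 * batch_means_se(sums)

    def test_unknown_column_rejected(self, rng):
        design, _, _ = make_design(seed=3)
        with pytest.raises(KeyError):
            sample_effect(design.m_total, _fixed_state(design), design, rng)


class TestConjugateDraws:
    def test_scaled_inv_chi2_moment(self, rng):
        draws = sample_scaled_inv_chi2(10.0, 2.0, rng, size=100_000)
        expected = 10 * 2 / (10 - 2)  # df*scale/(df-2)
        assert abs(draws.mean() - expected) / expected < 0.02

    def test_group_variance_prior_draw_when_empty(self, rng):
        hyper = Hyperparams()
        draws = np.array([
            sample_group_variance([], [], 0, hyper, rng) for _ in range(2000)
        ])
        assert np.all(draws > 0)
        assert draws.max() / draws.min() > 1e4  # heavy tails of the vague prior

    def test_group_variance_shrinks_with_zero_effects(self, rng):
        hyper = Hyperparams()
        draws = np.array([
            sample_group_variance(np.zeros(5), np.full(5, 0.01), 5, hyper, rng)
            for _ in range(2000)
        ])
        assert np.median(draws) < 1e-4

    def test_group_variance_scales_by_mixture_constant(self, rng):
        theta = np.full(40, 0.1)
        c = np.full(40, 0.01)
        draws = np.array([
            sample_group_variance(theta, c, 40, Hyperparams(), rng) for _ in range(20_000)
        ])
        # S_g = sum theta^2/C = 40; df = v0+40, scale = (S_g + v0*s0sq)/df
        df = 0.001 + 40
        scale = (40 + 0.001 * 0.001) / df
        expected = df * scale / (df - 2)
        assert abs(draws.mean() - expected) / expected < 0.02

    def test_dirichlet_posterior_mean(self, rng):
        draws = np.stack([
            sample_pi(np.array([96, 2, 1, 1]), np.ones(4), rng) for _ in range(100_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), np.array([97, 3, 2, 2]) / 104, atol=0.01)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_pi_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            sample_pi(np.array([1, 2]), np.ones(3), rng)

    def test_residual_variance_consistency(self, rng):
        n = 5000
        eps = np.random.default_rng(1).normal(size=n)
        eps *= np.sqrt(n) / np.linalg.norm(eps)  # eps'eps = N exactly
        draws = np.array([
            sample_residual_variance(eps, Hyperparams(), rng) for _ in range(3000)
        ])
        assert abs(draws.mean() - 1.0) < 0.05

    def test_residual_variance_zero_residual(self, rng):
        draws = np.array([
            sample_residual_variance(np.zeros(1000), Hyperparams(), rng)
            for _ in range(200)
        ])
        assert draws.mean() < 1e-4


class TestRunChain:
    def test_all_spike_matches_intercept_only_model(self):
        design, _, _ = make_design(n=200, m=10, seed=4)
        store = run_chain(design, iterations=3000, burn_in=1000, thin=2, seed=5,
                          fix_pi={"probes": [1.0, 0.0, 0.0, 0.0]})
        assert np.all(store.theta == 0.0)
        assert np.all(store.mix == 0)
        # sigma_eps posterior should match the intercept-only model: scale ~ Var(y)
        expected = design.y.var()
        assert abs(store.sigma_eps_sq.mean() - expected) < 0.1

    def test_deterministic_given_seed(self):
        design, _, _ = make_design(n=60, m=12, seed=6)
        a = run_chain(design, iterations=300, burn_in=100, thin=2, seed=42)
        b = run_chain(design, iterations=300, burn_in=100, thin=2, seed=42)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.sigma_eps_sq, b.sigma_eps_sq)
        np.testing.assert_array_equal(a.mix, b.mix)
        c = run_chain(design, iterations=300, burn_in=100, thin=2, seed=43)
        assert not np.array_equal(a.sigma_eps_sq, c.sigma_eps_sq)

    def test_saved_sample_count(self):
        design, _, _ = make_design(n=40, m=6, seed=8)
        store = run_chain(design, iterations=257, burn_in=100, thin=10, seed=1)
        assert store.n_samples == (257 - 100) // 10

    def test_residual_identity_over_thousand_iterations(self):
        design, _, _ = make_design(n=150, m=60, n_causal=6, seed=9)
        store = run_chain(design, iterations=1000, burn_in=500, thin=5, seed=2)
        assert store.meta["max_residual_deviation"] < 1e-8

    def test_column_permutation_leaves_posterior_invariant(self):
        design, _, _ = make_design(n=120, m=40, n_causal=5, seed=10)
        perm = np.random.default_rng(0).permutation(design.m_total)
        g = design.groups[0]
        design_p = GroupedDesign(
            y=design.y,
            groups=[CovariateGroup("probes", g.Z[:, perm], g.C,
                                   col_ids=[g.col_ids[j] for j in perm])],
        )
        a = run_chain(design, iterations=6000, burn_in=2000, thin=4, seed=11)
        b = run_chain(design_p, iterations=6000, burn_in=2000, thin=4, seed=12)
        # compare near-independent subsamples: KS assumes i.i.d. draws
        assert stats.ks_2samp(a.sigma_eps_sq[::10], b.sigma_eps_sq[::10]).pvalue > 0.01

    def test_invalid_schedules_rejected(self):
        design, _, _ = make_design(n=40, m=5, seed=13)
        with pytest.raises(ValueError):
            run_chain(design, iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            run_chain(design, iterations=100, burn_in=10, thin=0)

    def test_kernel_agrees_with_reference_updates(self, rng):
        """The compiled chain and a chain assembled from the plain-numpy
        conditional draws target the same posterior (means within MC error)."""
        design, _, _ = make_design(n=100, m=5, n_causal=2, ve=0.6, seed=14,
                                   C=(0.01, 0.1))
        store = run_chain(design, iterations=6000, burn_in=2000, thin=2, seed=3)

        st = SamplerState.initial(design)
        Z = design.full_matrix()
        gcol = np.zeros(design.m_total, dtype=int)
        zjtz = (Z**2).sum(axis=0)
        hyper = design.hyper
        kept_theta, kept_seps = [], []
        for it in range(6000):
            sample_intercept(st, design.y, rng)
            for j in rng.permutation(design.m_total):
                sample_effect(int(j), st, design, rng, Z=Z, group_of_col=gcol, zjtz=zjtz)
            st.sigma_eps_sq = sample_residual_variance(st.eps, hyper, rng)
            in_model = st.mix != 0
            c_of = np.where(in_model, design.groups[0].C[np.maximum(st.mix - 1, 0)], 1.0)
            st.sigma_g_sq[0] = sample_group_variance(
                st.theta[in_model], c_of[in_model], int(in_model.sum()), hyper, rng
            )
            counts = np.bincount(st.mix, minlength=3)
            st.pi_g[0] = sample_pi(counts, design.groups[0].dirichlet_prior, rng)
            if it >= 2000 and it % 2 == 0:
                kept_theta.append(st.theta.copy())
                kept_seps.append(st.sigma_eps_sq)
        ref_theta = np.array(kept_theta)
        for j in range(design.m_total):
            se = np.hypot(batch_means_se(store.theta[:, j]), batch_means_se(ref_theta[:, j]))
            assert abs(store.theta[:, j].mean() - ref_theta[:, j].mean()) < max(4 * se, 0.02)
        se = np.hypot(batch_means_se(store.sigma_eps_sq), batch_means_se(np.array(kept_seps)))
        assert abs(store.sigma_eps_sq.mean() - np.mean(kept_seps)) < max(4 * se, 0.02)


class TestJointOracle:
    def test_three_covariate_posterior_matches_joint_conditional(self, rng):
        """Single-site Gibbs means equal the exact joint slab conditional
        (all effects in one slab, variances held fixed)."""
        n = 80
        r = np.random.default_rng(21)
        Z = standardize(r.normal(size=(n, 3)) @ np.array(
            [[1, 0.4, 0.2], [0, 1, 0.3], [0, 0, 1]]))  # correlated columns
        beta = np.array([0.5, -0.3, 0.2])
        y = standardize_phenotype(Z @ beta + r.normal(size=n))
        s2, sg2 = 0.5, 0.8
        design = GroupedDesign(y=y, groups=[CovariateGroup("g", Z, (1.0,))])
        st = _fixed_state(design, sigma_eps_sq=s2, sigma_g_sq=sg2)
        st.pi_g[0] = np.array([0.0, 1.0])
        draws = np.empty((50_000, 3))
        for i in range(draws.shape[0]):
            for j in rng.permutation(3):
                sample_effect(int(j), st, design, rng)
            draws[i] = st.theta
        m_exact, V_exact = exact_slab_posterior(Z, y, s2, sg2)
        for j in range(3):
            se = batch_means_se(draws[:, j])
            assert abs(draws[:, j].mean() - m_exact[j]) < 3 * se
        np.testing.assert_allclose(np.cov(draws.T), V_exact, atol=0.02)


class TestScaling:
    def test_iteration_cost_linear_in_columns(self):
        """Doubling M should roughly double, not quadruple, iteration time."""
        times = {}
        for m in (300, 600):
            design, _, _ = make_design(n=150, m=m, n_causal=5, seed=15)
            run_chain(design, iterations=5, burn_in=1, thin=1, seed=1)  # warm
            t0 = time.perf_counter()
            run_chain(design, iterations=60, burn_in=10, thin=1, seed=1)
            times[m] = time.perf_counter() - t0
        assert times[600] / times[300] < 3.2
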