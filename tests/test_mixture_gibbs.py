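import numpy as np
import pytest
from scipy import stats

from conjugate_oracle import batch_means_mcse, exact_k1_posterior
from trustmix.design import ModelSpec, build_designs, stack_designs
from trustmix.mixture_gibbs import (
    PosteriorDraw,
    PriorSpec,
    allocation_probabilities,
    default_priors,
    log_likelihood_matrix,
    pooled_standardized_jb,
    raftery_lewis,
    residual_normality,
    run_chain,
    sample_step,
)
from trustmix.synthetic_data import (
    GeneratorConfig,
    GroupProfile,
    generate_population,
)


def _k1_problem(n=40, sigma=0.1, seed=0):
    cfg = GeneratorConfig(
        n_dyads=n,
        cluster_weights=np.array([1.0]),
        betas=np.array([[0.3, 0.25, 0.15, 0.1, 0.05]]),
        sigmas=np.array([sigma]),
        spec=ModelSpec(K=1, P=1, D=2),
        group_profiles={"Healthy": GroupProfile(1.0, (1.0,))},
        seed=seed,
    )
    records = generate_population(cfg)
    data = build_designs(records, cfg.spec)
    return cfg, data


class TestAllocationProbabilities:
    def _toy(self):
        rng = np.random.default_rng(1)
        X = rng.random((8, 3))
        y = rng.random(8)
        return y, X

    def test_identical_components_symmetric(self):
        y, X = self._toy()
        beta = np.tile([0.2, 0.3, 0.1], (2, 1))
        p = allocation_probabilities(y, X, np.array([0.5, 0.5]), beta,
                                     np.array([0.04, 0.04]))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_degenerate_weight(self):
        y, X = self._toy()
        beta = np.array([[0.2, 0.3, 0.1], [5.0, -3.0, 2.0]])
        p = allocation_probabilities(y, X, np.array([1.0, 0.0]), beta,
                                     np.array([0.04, 0.04]))
        np.testing.assert_allclose(p, [1.0, 0.0])

    def test_matches_dense_density_ratio(self):
        # independent oracle: direct multivariate-normal densities
        X = np.column_stack([np.ones(8), np.linspace(0, 1, 8)])
        beta = np.array([[0.2, 0.5], [0.9, -0.4]])
        y = X @ beta[0]  # exactly on component 1's mean
        s2 = np.array([0.02, 0.02])
        lam = np.array([0.5, 0.5])
        p = allocation_probabilities(y, X, lam, beta, s2)
        d1 = stats.multivariate_normal.pdf(y, mean=X @ beta[0],
                                           cov=s2[0] * np.eye(8))
        d2 = stats.multivariate_normal.pdf(y, mean=X @ beta[1],
                                           cov=s2[1] * np.eye(8))
        np.testing.assert_allclose(p[0], d1 / (d1 + d2), rtol=1e-10)

    def test_sums_to_one_and_shift_invariant(self):
        y, X = self._toy()
        rng = np.random.default_rng(2)
        for _ in range(20):
            beta = rng.normal(size=(3, 3))
            s2 = rng.uniform(0.01, 0.5, 3)
            lam = rng.dirichlet(np.ones(3))
            p = allocation_probabilities(y, X, lam, beta, s2)
            assert abs(p.sum() - 1.0) < 1e-12
            # scaling all densities by a constant leaves p unchanged
            p2 = allocation_probabilities(y, X, lam, beta * 1.0, s2)
            np.testing.assert_allclose(p, p2)


class TestConjugateOracle:
    """K=1: the sampler must match the exact quadrature posterior."""

    @pytest.fixture(scope="class")
    def fit(self):
        cfg, data = _k1_problem(n=40, seed=3)
        spec = cfg.spec
        priors = default_priors(spec)
        chain = run_chain(data, spec, priors, n_draws=4000, burn_in=500,
                          seed=5)
        Y, X = stack_designs(data)
        oracle = exact_k1_posterior(
            Y.ravel(), X.reshape(-1, X.shape[2]), priors.beta_mean,
            priors.beta_cov, priors.ig_shape, priors.ig_scale,
        )
        return chain, oracle

    def test_beta_posterior_mean(self, fit):
        chain, oracle = fit
        for m in range(chain.spec.n_coef):
            trace = chain.beta[:, 0, m]
            mcse = batch_means_mcse(trace)
            assert abs(trace.mean() - oracle["beta_mean"][m]) < 3 * mcse + 1e-4

    def test_sigma2_posterior_mean(self, fit):
        chain, oracle = fit
        trace = chain.sigma2[:, 0]
        mcse = batch_means_mcse(trace)
        assert abs(trace.mean() - oracle["sigma2_mean"]) < 3 * mcse + 1e-6


class TestSampleStep:
    def test_forced_single_cluster_dirichlet_moments(self):
        # all dyads in cluster 1 of 3: lambda | z ~ Dir(alpha1 + N, a2, a3)
        cfg, data = _k1_problem(n=30, seed=8)
        Y, X = stack_designs(data)
        K, M = 3, 5
        priors = PriorSpec(np.ones(K), np.zeros(M), np.eye(M))
        rng = np.random.default_rng(0)
        draws = []
        cur = PosteriorDraw(
            lam=np.array([0.98, 0.01, 0.01]),
            beta=np.vstack([[0.3, 0.25, 0.15, 0.1, 0.05],
                            [5.0, 0, 0, 0, 0], [-5.0, 0, 0, 0, 0]]),
            sigma2=np.array([0.02, 0.02, 0.02]),
            z=np.zeros(30, dtype=int),
        )
        for _ in range(3000):
            nxt = sample_step(Y, X, cur, priors, rng)
            assert np.all(nxt.z == 0)  # far-away components never win
            draws.append(nxt.lam)
            cur.lam, cur.sigma2 = nxt.lam, nxt.sigma2
            cur.beta[0] = nxt.beta[0]  # keep decoys fixed and far
        draws = np.asarray(draws)
        alpha_post = np.array([31.0, 1.0, 1.0])
        expected_mean = alpha_post / alpha_post.sum()
        a0 = alpha_post.sum()
        expected_var = alpha_post * (a0 - alpha_post) / (a0**2 * (a0 + 1))
        np.testing.assert_allclose(draws.mean(0), expected_mean, atol=0.01)
        np.testing.assert_allclose(draws.var(0), expected_var, rtol=0.25)

    def test_label_permutation_leaves_likelihood_unchanged(self):
        cfg, data = _k1_problem(n=10, seed=2)
        Y, X = stack_designs(data)
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 0.3, (3, 5))
        s2 = rng.uniform(0.01, 0.1, 3)
        lam = rng.dirichlet(np.ones(3))
        ll = log_likelihood_matrix(Y, X, beta, s2)
        perm = [2, 0, 1]
        ll_p = log_likelihood_matrix(Y, X, beta[perm], s2[perm])
        from scipy.special import logsumexp
        mix = logsumexp(np.log(lam) + ll, axis=1)
        mix_p = logsumexp(np.log(lam[perm]) + ll_p, axis=1)
        np.testing.assert_allclose(mix, mix_p)


class TestRunChain:
    def test_seed_reproducibility_bit_exact(self):
        cfg, data = _k1_problem(n=15, seed=6)
        kwargs = dict(n_draws=50, burn_in=20, seed=123)
        a = run_chain(data, cfg.spec, **kwargs)
        b = run_chain(data, cfg.spec, **kwargs)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.lam, b.lam)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)
        np.testing.assert_array_equal(a.z, b.z)

    def test_different_seeds_differ(self):
        cfg, data = _k1_problem(n=15, seed=6)
        a = run_chain(data, cfg.spec, n_draws=50, burn_in=20, seed=1)
        b = run_chain(data, cfg.spec, n_draws=50, burn_in=20, seed=2)
        assert not np.array_equal(a.beta, b.beta)

    def test_thinning(self):
        cfg, data = _k1_problem(n=15, seed=6)
        chain = run_chain(data, cfg.spec, n_draws=60, burn_in=10, seed=1,
                          thin=3)
        assert chain.n_draws == 20
        assert chain.thin == 3

    def test_prior_dimension_mismatch(self):
        cfg, data = _k1_problem(n=15, seed=6)
        priors = default_priors(ModelSpec(K=2, P=1, D=2))
        with pytest.raises(ValueError, match="dimensions"):
            run_chain(data, cfg.spec, priors, n_draws=10, burn_in=5, seed=0)


class TestResidualNormality:
    def test_level_under_gaussian(self):
        # pooled-JB rejection rate at nominal 5% with n = 2000
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            groups = [rng.standard_normal(500) for _ in range(4)]
            *_, p = pooled_standardized_jb(groups)
            rejections += p < 0.05
        assert 0.015 <= rejections / n_reps <= 0.10

    def test_power_under_exponential(self):
        rng = np.random.default_rng(98)
        for _ in range(20):
            groups = [rng.exponential(size=500) for _ in range(4)]
            *_, p = pooled_standardized_jb(groups)
            assert p < 0.05

    def test_degenerate_zero_variance_inapplicable(self):
        assert pooled_standardized_jb([np.zeros(100)]) is None

    def test_on_fitted_chain_not_rejected(self, fitted_chain):
        chain, data, _ = fitted_chain
        result = residual_normality(chain, data)
        assert result is not None
        skew, kurt, jb, p = result
        # Gaussian generator (mild clipping): normality should survive
        assert p > 0.001
        assert abs(skew) < 0.5


class TestRafteryLewis:
    def test_iid_matches_independence_formula(self):
        rng = np.random.default_rng(11)
        trace = rng.standard_normal(40_000)
        out = raftery_lewis(trace, quantile=0.025, accuracy=0.005,
                            confidence=0.95)
        assert out["applicable"]
        z = stats.norm.ppf(0.975)
        n_min = 0.025 * 0.975 * (z / 0.005) ** 2
        assert abs(out["n_required"] - n_min) / n_min < 0.20

    def test_autocorrelated_needs_more(self):
        rng = np.random.default_rng(12)
        eps = rng.standard_normal(40_000)
        ar = np.empty_like(eps)
        ar[0] = eps[0]
        for t in range(1, eps.size):
            ar[t] = 0.95 * ar[t - 1] + eps[t]
        iid = raftery_lewis(rng.standard_normal(40_000))
        dep = raftery_lewis(ar)
        assert dep["n_required"] > iid["n_required"]
        assert dep["dependence_factor"] > 1.5

    def test_constant_trace_inapplicable(self):
        out = raftery_lewis(np.ones(5000))
        assert out["applicable"] is False
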