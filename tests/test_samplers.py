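"""Sampler correctness: conjugate closed forms, exact enumeration, priors.

The oracles here are independent of the Gibbs implementations: ridge-type
posteriors are solved with dense linear algebra, posterior inclusion
probabilities on tiny problems by exhaustive enumeration of indicator
configurations with conjugate Gaussian marginal likelihoods, and the
BLASSO prior by its closed-form Laplace marginal.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from bayesgp import (
    BlassoPrior,
    BlmmPrior,
    BslmmPrior,
    McmcSettings,
    SpikeSlabPrior,
    compute_kinship,
    fit_blasso,
    fit_blmm,
    fit_bslmm,
    fit_spike_slab,
    pip,
    sample_blasso_prior_beta,
)
from bayesgp.diagnostics import effective_sample_size


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ridge_posterior(Xc, yc, prior_var, noise_var):
    """Closed-form Gaussian posterior for beta under an iid normal prior."""
    p = Xc.shape[1]
    A = Xc.T @ Xc / noise_var + np.eye(p) / prior_var
    cov = np.linalg.inv(A)
    return cov @ (Xc.T @ yc) / noise_var, cov


def enumerate_pips(Xc, yc, slab_var, spike_var, noise_var, pi0):
    """Exact P(gamma_j = 1 | y) by summing over all 2^p configurations.

    ``spike_var=0`` gives the point-mass spike (BSLMM-style); a positive
    value gives the continuous spike.  Marginal likelihoods are Gaussian:
    y ~ N(0, X V X^T + noise_var I) with V diagonal per configuration.
    """
    n, p = Xc.shape
    log_post = {}
    for gam in itertools.product((0, 1), repeat=p):
        V = np.array([slab_var if g else spike_var for g in gam])
        C = Xc @ (V[:, None] * Xc.T) + noise_var * np.eye(n)
        _, logdet = np.linalg.slogdet(C)
        ll = -0.5 * (logdet + yc @ np.linalg.solve(C, yc))
        lp = sum(np.log(pi0) if g else np.log(1 - pi0) for g in gam)
        log_post[gam] = ll + lp
    mx = max(log_post.values())
    weights = {g: np.exp(v - mx) for g, v in log_post.items()}
    Z = sum(weights.values())
    return np.array(
        [sum(w for g, w in weights.items() if g[j]) / Z for j in range(p)]
    )


def mc_se(draws_1d):
    """Monte Carlo standard error from the autocorrelation-adjusted ESS."""
    ess = effective_sample_size(draws_1d[None, :])
    return draws_1d.std() / np.sqrt(max(ess, 1.0))


@pytest.fixture(scope="module")
def toy_25x2():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(25, 2))
    y = X @ np.array([0.8, 0.0]) + rng.normal(0, 1, 25)
    return X, y


# ---------------------------------------------------------------------------
# spike-and-slab
# ---------------------------------------------------------------------------

class TestSpikeSlab:
    def test_default_hyperparameters(self):
        prior = SpikeSlabPrior()
        assert (prior.v0, prior.v1) == (0.00025, 1.0)
        assert (prior.nu, prior.lam) == (10.0, 125.0)
        assert (prior.a, prior.b) == (0.001, 0.001)
        assert prior.pi0 == 0.5

    def test_conjugate_limit_matches_ridge_posterior(self):
        """v0 = v1 = v with fixed variances collapses to a ridge posterior."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, -0.5, 0.0]) + rng.normal(0, 1, 50)
        v, s2, se2 = 0.5, 1.0, 1.0
        prior = SpikeSlabPrior(v0=v, v1=v, sigma2_fixed=s2, sigma_eps2_fixed=se2)
        samp = fit_spike_slab(
            X, y, prior, McmcSettings(n_chains=2, n_iter=4000, burn_in=500, seed=3)
        )
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        mean, cov = ridge_posterior(Xc, yc, v * s2, se2)
        for j in range(3):
            se = mc_se(samp.beta_draws[:, j])
            assert abs(samp.beta_draws[:, j].mean() - mean[j]) < 3 * se + 1e-3
            assert samp.beta_draws[:, j].std() == pytest.approx(
                np.sqrt(cov[j, j]), rel=0.15
            )

    def test_pips_match_enumeration_oracle(self, toy_25x2):
        X, y = toy_25x2
        v0, v1, s2, se2 = 1e-4, 1.0, 1.0, 1.0
        prior = SpikeSlabPrior(v0=v0, v1=v1, sigma2_fixed=s2, sigma_eps2_fixed=se2)
        samp = fit_spike_slab(
            X, y, prior, McmcSettings(n_chains=3, n_iter=11000, burn_in=1000, seed=5)
        )
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        exact = enumerate_pips(Xc, yc, v1 * s2, v0 * s2, se2, prior.pi0)
        assert np.abs(pip(samp) - exact).max() < 0.02

    def test_reproducible_and_variances_positive(self, toy_25x2):
        X, y = toy_25x2
        settings = McmcSettings(n_chains=2, n_iter=300, burn_in=100, seed=9)
        a = fit_spike_slab(X, y, settings=settings)
        b = fit_spike_slab(X, y, settings=settings)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.gamma_draws, b.gamma_draws)
        for draws in a.variance_draws.values():
            assert np.all(draws > 0)

    def test_retained_draw_count(self, toy_25x2):
        X, y = toy_25x2
        samp = fit_spike_slab(
            X, y, settings=McmcSettings(n_chains=2, n_iter=500, burn_in=200, thin=3, seed=1)
        )
        assert samp.n_draws == 2 * (300 // 3)


# ---------------------------------------------------------------------------
# Bayesian LASSO
# ---------------------------------------------------------------------------

class TestBlasso:
    def test_default_hyperparameters(self):
        prior = BlassoPrior()
        assert prior.a_lambda == 0.55
        assert prior.b_lambda == 1e-6
        assert prior.a_sigma == prior.b_sigma == 0.5

    def test_prior_hierarchy_is_laplace(self):
        """Ancestral scale-mixture draws follow the Laplace(lambda) law (KS)."""
        lam = 1.7
        draws = sample_blasso_prior_beta(lam, n_draws=100_000, seed=2)
        ks = stats.kstest(draws, stats.laplace(scale=1 / lam).cdf)
        assert ks.pvalue > 0.01

    def test_large_lambda_shrinks_coefficients(self, toy_25x2):
        X, y = toy_25x2
        settings = McmcSettings(n_chains=1, n_iter=2000, burn_in=500, seed=4)
        loose = fit_blasso(X, y, BlassoPrior(lambda_fixed=0.01), settings)
        tight = fit_blasso(X, y, BlassoPrior(lambda_fixed=100.0), settings)
        norm_loose = np.abs(loose.beta_draws.mean(axis=0)).sum()
        norm_tight = np.abs(tight.beta_draws.mean(axis=0)).sum()
        assert norm_tight < norm_loose

    def test_lambda_and_sigma2_draws_positive(self, toy_25x2):
        X, y = toy_25x2
        samp = fit_blasso(X, y, settings=McmcSettings(1, 400, 100, seed=6))
        assert np.all(samp.variance_draws["lambda"] > 0)
        assert np.all(samp.variance_draws["sigma2"] > 0)
        assert samp.gamma_draws is None

    def test_pip_unsupported(self, toy_25x2):
        X, y = toy_25x2
        samp = fit_blasso(X, y, settings=McmcSettings(1, 200, 100, seed=6))
        with pytest.raises(ValueError, match="blasso"):
            pip(samp)


# ---------------------------------------------------------------------------
# Bayesian LMM
# ---------------------------------------------------------------------------

class TestBlmm:
    def test_vanishing_polygenic_variance_matches_ridge(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([0.5, -0.5, 0.2, 0.0]) + rng.normal(0, 1, 60)
        prior = BlmmPrior(tau2=2.0, sigma2_fixed=1.0, sigma_u2_fixed=1e-10)
        samp = fit_blmm(X, y, prior, McmcSettings(2, 3000, 500, seed=2))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        mean, _ = ridge_posterior(Xc, yc, 2.0, 1.0)
        for j in range(4):
            se = mc_se(samp.beta_draws[:, j])
            assert abs(samp.beta_draws[:, j].mean() - mean[j]) < 3 * se + 1e-3

    def test_flat_prior_limit_approaches_least_squares(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, 0.5, -0.7]) + rng.normal(0, 0.5, 80)
        prior = BlmmPrior(tau2=1e6, sigma_u2_fixed=1e-10)
        samp = fit_blmm(X, y, prior, McmcSettings(2, 3000, 500, seed=3))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        ols = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        for j in range(3):
            se = mc_se(samp.beta_draws[:, j])
            assert abs(samp.beta_draws[:, j].mean() - ols[j]) < 3 * se + 1e-3

    def test_markerless_animal_model_u_shrinks_with_prior(self):
        """p=0: u posterior shrinks toward zero as the sigma_u2 prior collapses."""
        rng = np.random.default_rng(23)
        G_src = rng.normal(size=(30, 50))
        G_src -= G_src.mean(axis=0)
        K = compute_kinship(G_src, denominator="p")
        y = rng.normal(size=30)
        X0 = np.empty((30, 0))
        free = fit_blmm(X0, y, BlmmPrior(), McmcSettings(1, 1500, 500, seed=4), kinship=K)
        tight = fit_blmm(
            X0, y, BlmmPrior(sigma_u2_fixed=1e-8),
            McmcSettings(1, 1500, 500, seed=4), kinship=K,
        )
        assert np.abs(tight.u_draws.mean(axis=0)).max() < np.abs(free.u_draws.mean(axis=0)).max()
        assert np.abs(tight.u_draws.mean(axis=0)).max() < 1e-2


# ---------------------------------------------------------------------------
# BSLMM
# ---------------------------------------------------------------------------

class TestBslmm:
    def test_default_hyperparameters(self):
        prior = BslmmPrior()
        assert (prior.alpha_a, prior.gamma_a) == (10.0, 0.01)
        assert (prior.alpha_b, prior.gamma_b) == (10.0, 0.01)
        assert prior.alpha_eps == prior.gamma_eps == 0.001
        assert prior.sigma_mu2 is None  # recomputed from y at fit time

    def test_point_mass_pips_match_enumeration(self, toy_25x2):
        """No polygenic term + fixed variances: exact 2^p enumeration."""
        X, y = toy_25x2
        yc = y - y.mean()
        sa2, se2, pi0 = 1.0, 1.0, 0.5
        prior = BslmmPrior(
            pi_fixed=pi0, sigma_a2_fixed=sa2, sigma_b2_fixed=0.0,
            sigma_eps2_fixed=se2, sigma_mu2=1e-12,
        )
        samp = fit_bslmm(
            X, yc, prior, McmcSettings(n_chains=2, n_iter=6000, burn_in=1000, seed=7)
        )
        Xc = X - X.mean(axis=0)
        exact = enumerate_pips(Xc, yc, sa2, 0.0, se2, pi0)
        assert np.abs(pip(samp) - exact).max() < 0.03

    def test_forced_full_inclusion_matches_ridge(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([0.7, 0.0, -0.4]) + rng.normal(0, 1, 50)
        prior = BslmmPrior(
            pi_fixed=1.0, sigma_a2_fixed=0.8, sigma_b2_fixed=0.0,
            sigma_eps2_fixed=1.0, sigma_mu2=1e-12,
        )
        samp = fit_bslmm(
            X, y - y.mean(), prior, McmcSettings(2, 4000, 500, seed=8)
        )
        assert np.all(samp.gamma_draws == 1)
        Xc = X - X.mean(axis=0)
        mean, _ = ridge_posterior(Xc, y - y.mean(), 0.8, 1.0)
        for j in range(3):
            se = mc_se(samp.beta_draws[:, j])
            assert abs(samp.beta_draws[:, j].mean() - mean[j]) < 3 * se + 1e-3

    def test_pi_draws_respect_support_and_moves(self, toy_25x2):
        X, y = toy_25x2
        samp = fit_bslmm(X, y, settings=McmcSettings(1, 1500, 500, seed=9))
        pi_draws = samp.variance_draws["pi"]
        p = X.shape[1]
        assert np.all(pi_draws >= 1 / p - 1e-12)
        assert np.all(pi_draws <= 1.0)
        assert samp.meta["pi_acceptance"] > 0
        assert len(np.unique(pi_draws)) > 10  # the Metropolis chain moves

    def test_reproducible(self, toy_25x2):
        X, y = toy_25x2
        settings = McmcSettings(1, 400, 100, seed=10)
        a = fit_bslmm(X, y, settings=settings)
        b = fit_bslmm(X, y, settings=settings)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.variance_draws["pi"], b.variance_draws["pi"])


class TestKinship:
    def test_zero_matrix(self):
        K = compute_kinship(np.zeros((4, 3)))
        assert np.all(K == 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(12, 7))
        X -= X.mean(axis=0)
        K = compute_kinship(X, denominator="p")
        brute = np.zeros((12, 12))
        for i in range(12):
            for k in range(12):
                brute[i, k] = sum(X[i, j] * X[k, j] for j in range(7)) / 7
        assert np.abs(K - brute).max() < 1e-10

    def test_denominator_n(self):
        X = np.diag([1.0, -1.0]) - 0.0  # already column-centered? no: center it
        X = X - X.mean(axis=0)
        K = compute_kinship(X, denominator="n")
        assert np.allclose(K, X @ X.T / 2)

    def test_non_centered_warns(self):
        with pytest.warns(UserWarning, match="centered"):
            compute_kinship(np.ones((3, 2)))

    def test_psd(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 4))
        X -= X.mean(axis=0)
        vals = np.linalg.eigvalsh(compute_kinship(X))
        assert vals.min() > -1e-10
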