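"""Component-wise Gibbs samplers for four Bayesian genomic-prediction models.

All four models regress a quantitative trait y on genome-wide marker
dosages X (n individuals x p SNPs) and differ in the prior on the marker
effects beta and in whether a kinship-correlated polygenic term is present:

* ``fit_spike_slab`` — continuous spike-and-slab (SSVS): beta_j is Gaussian
  with variance gamma_j v1 sigma^2 + (1-gamma_j) v0 sigma^2, gamma_j
  Bernoulli(pi); induces variable selection via posterior inclusion
  probabilities.
* ``fit_blasso`` — Bayesian LASSO: Laplace(rate lambda) prior on beta_j,
  sampled through its normal–exponential scale-mixture representation with
  inverse-Gaussian latent updates; Gamma hyperprior on lambda^2.
* ``fit_blmm`` — Bayesian linear mixed model: iid Gaussian beta plus a
  polygenic effect u ~ N(0, G sigma_u^2) with G the kinship matrix.
* ``fit_bslmm`` — Bayesian sparse LMM: point-mass-at-zero plus Gaussian
  slab on beta (marginalized two-state updates), a polygenic term
  u ~ N(0, sigma_b^2 K), an explicit intercept mu, and a uniform-on-log
  prior on the inclusion probability pi updated by random-walk Metropolis.

Single-site beta updates maintain a running residual vector; the update
order is a fresh random permutation each iteration.  Chains are
independent given their seeds (derived from ``McmcSettings.seed`` and the
chain index); identical inputs reproduce identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinship import compute_kinship, kinship_eigh
from .types import GenotypeMatrix, PosteriorSamples, TrainContext

__all__ = [
    "SpikeSlabPrior",
    "BlassoPrior",
    "BlmmPrior",
    "BslmmPrior",
    "McmcSettings",
    "fit_spike_slab",
    "fit_blasso",
    "fit_blmm",
    "fit_bslmm",
    "pip",
]

_VAR_FLOOR = 1e-12   # positivity floor for variance draws
_BETA_FLOOR = 1e-10  # guard for the inverse-Gaussian latent update


# ---------------------------------------------------------------------------
# priors and settings
# ---------------------------------------------------------------------------

@dataclass
class SpikeSlabPrior:
    """Continuous spike-and-slab hierarchy.

    beta_j | gamma_j, sigma2 ~ N(0, [gamma_j v1 + (1-gamma_j) v0] sigma2),
    gamma_j ~ Bernoulli(pi0), sigma2 ~ IG(nu/2, nu*lam/2),
    sigma_eps2 ~ IG(a, b).  ``sigma2_fixed``/``sigma_eps2_fixed`` clamp a
    variance at a known value (degenerate prior), used for conjugate-limit
    and enumeration checks.
    """

    v0: float = 0.00025
    v1: float = 1.0
    nu: float = 10.0
    lam: float = 125.0
    a: float = 0.001
    b: float = 0.001
    pi0: float = 0.5
    sigma2_fixed: Optional[float] = None
    sigma_eps2_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.v0 <= self.v1):
            raise ValueError("require 0 < v0 <= v1")
        if not (0 < self.pi0 < 1):
            raise ValueError("pi0 must be in (0, 1)")
        for name in ("nu", "lam", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BlassoPrior:
    """Bayesian LASSO: beta_j ~ Laplace(0, rate lambda), lambda^2 ~ Gamma.

    The Gamma(a_lambda, b_lambda) hyperprior (shape, rate) is placed on
    lambda^2, the parameterization under which the update is conjugate.
    """

    a_lambda: float = 0.55
    b_lambda: float = 1e-6
    a_sigma: float = 0.5
    b_sigma: float = 0.5
    lambda_fixed: Optional[float] = None
    sigma2_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("a_lambda", "b_lambda", "a_sigma", "b_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BlmmPrior:
    """Bayesian LMM: beta_j ~ N(0, tau2) fixed-variance, u ~ N(0, G sigma_u2).

    tau2 is a fixed configuration value; sigma2 and sigma_u2 carry
    inverse-gamma priors.  Z is the identity (one random effect per
    individual); G is the kinship of the training genotypes unless
    supplied.
    """

    tau2: float = 1.0
    a_sigma: float = 0.001
    b_sigma: float = 0.001
    a_u: float = 0.001
    b_u: float = 0.001
    kinship_source: str = "genotypes"  # or "supplied"
    kinship_denominator: str = "n"
    sigma2_fixed: Optional[float] = None
    sigma_u2_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tau2", "a_sigma", "b_sigma", "a_u", "b_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BslmmPrior:
    """Bayesian sparse LMM: point-mass + slab effects over a polygenic term.

    beta_j ~ pi N(0, sigma_a2) + (1-pi) delta0, u ~ N(0, sigma_b2 K),
    mu ~ N(0, sigma_mu2) with sigma_mu2 the phenotype variance (recomputed
    from y at fit time when left None), log(pi) ~ Uniform(log(1/p), 0).
    """

    alpha_a: float = 10.0
    gamma_a: float = 0.01
    alpha_b: float = 10.0
    gamma_b: float = 0.01
    alpha_eps: float = 0.001
    gamma_eps: float = 0.001
    sigma_mu2: Optional[float] = None
    kinship_denominator: str = "n"
    pi_fixed: Optional[float] = None
    sigma_a2_fixed: Optional[float] = None
    sigma_b2_fixed: Optional[float] = None
    sigma_eps2_fixed: Optional[float] = None
    pi_proposal_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha_a", "gamma_a", "alpha_b", "gamma_b", "alpha_eps", "gamma_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class McmcSettings:
    """Chains, iterations, burn-in, thinning, master seed."""

    n_chains: int = 3
    n_iter: int = 8000
    burn_in: int = 3000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @classmethod
    def final_run(cls, seed: int = 0) -> "McmcSettings":
        """Long single-chain production settings (20,000 retained draws)."""
        return cls(n_chains=1, n_iter=25000, burn_in=5000, thin=1, seed=seed)

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _prepare_xy(X, y, center_y: bool):
    """Center columns of X (and optionally y); return fit-ready arrays."""
    if isinstance(X, GenotypeMatrix):
        marker_ids = list(X.marker_ids)
        X = X.dosages
    else:
        X = np.asarray(X)
        marker_ids = [f"m{j}" for j in range(X.shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite with no missing values")
    col_means = X.mean(axis=0)
    Xc = np.asfortranarray(X - col_means)  # column views are contiguous
    y_offset = float(y.mean()) if center_y else 0.0
    yc = y - y_offset
    ctx = TrainContext(marker_ids=marker_ids, col_means=col_means, y_offset=y_offset)
    return Xc, yc, ctx


def _chain_rngs(settings: McmcSettings):
    return [
        np.random.default_rng(np.random.SeedSequence([int(settings.seed), c]))
        for c in range(settings.n_chains)
    ]


def _draw_ig(rng, shape: float, scale: float) -> float:
    """One draw from InverseGamma(shape, scale)."""
    return max(scale / rng.gamma(shape), _VAR_FLOOR)


def _retain_mask(settings: McmcSettings) -> np.ndarray:
    it = np.arange(settings.n_iter)
    return (it >= settings.burn_in) & ((it - settings.burn_in) % settings.thin == 0)


def _sample_inverse_gaussian(rng, mu: np.ndarray, lam: float) -> np.ndarray:
    """Vectorized inverse-Gaussian draws (Michael–Schucany–Haas)."""
    z = rng.standard_normal(mu.shape)
    w = z * z
    x = mu + mu * mu * w / (2 * lam) - (mu / (2 * lam)) * np.sqrt(
        4 * mu * lam * w + (mu * w) ** 2
    )
    x = np.maximum(x, _VAR_FLOOR)
    use_x = rng.random(mu.shape) < mu / (mu + x)
    return np.where(use_x, x, mu * mu / x)


def sample_blasso_prior_beta(
    lam: float, n_draws: int, seed: int = 0
) -> np.ndarray:
    """Ancestral draws of beta_j from the BLASSO scale-mixture hierarchy.

    tau2 ~ Exp(rate lambda^2/2), beta | tau2 ~ N(0, tau2); marginally
    beta ~ Laplace(0, rate lambda).  Used for prior-predictive checks of
    the hierarchy the Gibbs sampler targets.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    tau2 = rng.exponential(scale=2.0 / lam**2, size=n_draws)
    return rng.standard_normal(n_draws) * np.sqrt(tau2)


def pip(samples: PosteriorSamples) -> np.ndarray:
    """Posterior inclusion probability per marker (mean of indicators)."""
    if samples.gamma_draws is None:
        raise ValueError(
            f"model {samples.model_tag!r} has no inclusion indicators; "
            "PIPs are defined for spike_slab and bslmm only"
        )
    return samples.gamma_draws.mean(axis=0)


# ---------------------------------------------------------------------------
# spike-and-slab
# ---------------------------------------------------------------------------

def fit_spike_slab(
    X, y, prior: SpikeSlabPrior | None = None, settings: McmcSettings | None = None
) -> PosteriorSamples:
    """Gibbs sampler for the continuous spike-and-slab regression.

    Per iteration: (i) each beta_j from its Gaussian full conditional
    given the running residual and its current indicator; (ii) each
    gamma_j from a Bernoulli whose odds multiply pi0/(1-pi0) by the ratio
    of slab/spike Gaussian densities at the current beta_j; (iii) sigma2
    from IG(nu/2 + p/2, [nu lam + sum beta_j^2/v_j]/2); (iv) sigma_eps2
    from IG(a + n/2, b + ||r||^2/2).  y is centered before fitting (the
    model has no intercept term); the removed mean is restored at
    prediction time.
    """
    prior = prior or SpikeSlabPrior()
    settings = settings or McmcSettings()
    Xc, yc, ctx = _prepare_xy(X, y, center_y=True)
    n, p = Xc.shape
    if p < 1:
        raise ValueError("spike_slab requires at least one marker")
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    retain = _retain_mask(settings)
    L_chain = int(retain.sum())

    v0, v1, pi0 = prior.v0, prior.v1, prior.pi0
    log_prior_odds = np.log(pi0) - np.log1p(-pi0)

    beta_out, gamma_out, s2_out, se2_out, chain_out = [], [], [], [], []
    for c, rng in enumerate(_chain_rngs(settings)):
        beta = np.zeros(p)
        gamma = (rng.random(p) < pi0).astype(np.int8)
        # over-dispersed starts across chains
        sigma2 = prior.sigma2_fixed or float(
            prior.lam * (0.5 + c)
        )
        sigma_eps2 = prior.sigma_eps2_fixed or float(np.var(yc) * (0.5 + 0.5 * c) + 0.1)
        r = yc - Xc @ beta

        bdraws = np.empty((L_chain, p))
        gdraws = np.empty((L_chain, p), dtype=np.int8)
        s2draws = np.empty(L_chain)
        se2draws = np.empty(L_chain)
        kept = 0
        for it in range(settings.n_iter):
            inv_se2 = 1.0 / sigma_eps2
            order = rng.permutation(p)
            for j in order:
                xj = Xc[:, j]
                bj = beta[j]
                vj = (v1 if gamma[j] else v0) * sigma2
                prec = xtx[j] * inv_se2 + 1.0 / vj
                mean = (xj @ r + xtx[j] * bj) * inv_se2 / prec
                bnew = mean + rng.standard_normal() / np.sqrt(prec)
                r -= xj * (bnew - bj)
                beta[j] = bnew
            # vectorized indicator update given current beta
            b2 = beta * beta
            log_ratio = (
                log_prior_odds
                + 0.5 * np.log(v0 / v1)
                + 0.5 * b2 / sigma2 * (1.0 / v0 - 1.0 / v1)
            )
            p_incl = 1.0 / (1.0 + np.exp(-np.clip(log_ratio, -700, 700)))
            gamma = (rng.random(p) < p_incl).astype(np.int8)

            if prior.sigma2_fixed is None:
                vj_unit = np.where(gamma == 1, v1, v0)
                sigma2 = _draw_ig(
                    rng,
                    0.5 * (prior.nu + p),
                    0.5 * (prior.nu * prior.lam + float(np.sum(b2 / vj_unit))),
                )
            if prior.sigma_eps2_fixed is None:
                sigma_eps2 = _draw_ig(rng, prior.a + 0.5 * n, prior.b + 0.5 * float(r @ r))

            if retain[it]:
                bdraws[kept] = beta
                gdraws[kept] = gamma
                s2draws[kept] = sigma2
                se2draws[kept] = sigma_eps2
                kept += 1
        beta_out.append(bdraws)
        gamma_out.append(gdraws)
        s2_out.append(s2draws)
        se2_out.append(se2draws)
        chain_out.append(np.full(L_chain, c))

    return PosteriorSamples(
        model_tag="spike_slab",
        beta_draws=np.vstack(beta_out),
        gamma_draws=np.vstack(gamma_out),
        variance_draws={
            "sigma2": np.concatenate(s2_out),
            "sigma_eps2": np.concatenate(se2_out),
        },
        chain_ids=np.concatenate(chain_out),
        context=ctx,
        meta={"settings": settings, "prior": prior},
    )


# ---------------------------------------------------------------------------
# Bayesian LASSO
# ---------------------------------------------------------------------------

def fit_blasso(
    X, y, prior: BlassoPrior | None = None, settings: McmcSettings | None = None
) -> PosteriorSamples:
    """Gibbs sampler for the Bayesian LASSO via the scale-mixture form.

    beta_j | tau_j^2 ~ N(0, tau_j^2) with tau_j^2 ~ Exp(lambda^2/2)
    marginalizes to Laplace(rate lambda).  Updates: beta_j Gaussian full
    conditionals (running residual); 1/tau_j^2 inverse-Gaussian with mean
    lambda/|beta_j| (|beta_j| floored at 1e-10) and shape lambda^2;
    sigma2 from IG(a_sigma + n/2, b_sigma + ||r||^2/2); lambda^2 from
    Gamma(a_lambda + p, rate b_lambda + sum tau_j^2 / 2).
    """
    prior = prior or BlassoPrior()
    settings = settings or McmcSettings()
    Xc, yc, ctx = _prepare_xy(X, y, center_y=True)
    n, p = Xc.shape
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    retain = _retain_mask(settings)
    L_chain = int(retain.sum())

    beta_out, s2_out, lam_out, chain_out = [], [], [], []
    for c, rng in enumerate(_chain_rngs(settings)):
        beta = np.zeros(p)
        tau2 = np.ones(p)
        sigma2 = prior.sigma2_fixed or float(np.var(yc) * (0.5 + 0.5 * c) + 0.1)
        lam = prior.lambda_fixed or float(1.0 + c)
        r = yc - Xc @ beta

        bdraws = np.empty((L_chain, p))
        s2draws = np.empty(L_chain)
        lamdraws = np.empty(L_chain)
        kept = 0
        for it in range(settings.n_iter):
            inv_s2 = 1.0 / sigma2
            order = rng.permutation(p)
            for j in order:
                xj = Xc[:, j]
                bj = beta[j]
                prec = xtx[j] * inv_s2 + 1.0 / tau2[j]
                mean = (xj @ r + xtx[j] * bj) * inv_s2 / prec
                bnew = mean + rng.standard_normal() / np.sqrt(prec)
                r -= xj * (bnew - bj)
                beta[j] = bnew

            abs_beta = np.maximum(np.abs(beta), _BETA_FLOOR)
            inv_tau2 = _sample_inverse_gaussian(rng, lam / abs_beta, lam * lam)
            tau2 = 1.0 / np.maximum(inv_tau2, _VAR_FLOOR)

            if prior.sigma2_fixed is None:
                sigma2 = _draw_ig(
                    rng, prior.a_sigma + 0.5 * n, prior.b_sigma + 0.5 * float(r @ r)
                )
            if prior.lambda_fixed is None:
                lam2 = rng.gamma(
                    prior.a_lambda + p, 1.0 / (prior.b_lambda + 0.5 * float(tau2.sum()))
                )
                lam = float(np.sqrt(max(lam2, _VAR_FLOOR)))

            if retain[it]:
                bdraws[kept] = beta
                s2draws[kept] = sigma2
                lamdraws[kept] = lam
                kept += 1
        beta_out.append(bdraws)
        s2_out.append(s2draws)
        lam_out.append(lamdraws)
        chain_out.append(np.full(L_chain, c))

    return PosteriorSamples(
        model_tag="blasso",
        beta_draws=np.vstack(beta_out),
        variance_draws={
            "sigma2": np.concatenate(s2_out),
            "lambda": np.concatenate(lam_out),
        },
        chain_ids=np.concatenate(chain_out),
        context=ctx,
        meta={"settings": settings, "prior": prior},
    )


# ---------------------------------------------------------------------------
# polygenic-term helpers (BLMM, BSLMM)
# ---------------------------------------------------------------------------

def _update_polygenic(rng, resid_wo_u, evals, evecs, sigma_e2, sigma_u2):
    """Draw u | rest in the kinship eigenbasis; returns (u, coords d)."""
    t = evecs.T @ resid_wo_u
    pos = evals > 0
    d = np.zeros_like(t)
    if pos.any():
        prec = 1.0 / sigma_e2 + 1.0 / (sigma_u2 * evals[pos])
        mean = (t[pos] / sigma_e2) / prec
        d[pos] = mean + rng.standard_normal(int(pos.sum())) / np.sqrt(prec)
    return evecs @ d, d


def _update_sigma_u2(rng, d, evals, a, b):
    pos = evals > 0
    ss = float(np.sum(d[pos] ** 2 / evals[pos]))
    return _draw_ig(rng, a + 0.5 * int(pos.sum()), b + 0.5 * ss)


# ---------------------------------------------------------------------------
# Bayesian linear mixed model
# ---------------------------------------------------------------------------

def fit_blmm(
    X,
    y,
    prior: BlmmPrior | None = None,
    settings: McmcSettings | None = None,
    kinship: np.ndarray | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for the Bayesian LMM with marker effects + kinship term.

    beta_j full conditionals are Gaussian with fixed prior variance tau2;
    u is drawn in the eigenbasis of G (kinship of the centered training
    dosages unless ``kinship`` is supplied); sigma2 and sigma_u2 from
    their inverse-gamma full conditionals.  p = 0 (no markers) reduces to
    a kinship-only animal model.
    """
    prior = prior or BlmmPrior()
    settings = settings or McmcSettings()
    Xc, yc, ctx = _prepare_xy(X, y, center_y=True)
    n, p = Xc.shape
    if kinship is not None:
        G = np.asarray(kinship, dtype=float)
    else:
        G = compute_kinship(Xc, denominator=prior.kinship_denominator)
    if G.shape != (n, n):
        raise ValueError(f"kinship must be {n}x{n}")
    evals, evecs = kinship_eigh(G)
    ctx.X_train_centered = Xc
    ctx.kinship_denominator = prior.kinship_denominator
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    retain = _retain_mask(settings)
    L_chain = int(retain.sum())

    beta_out, u_out, s2_out, su2_out, chain_out = [], [], [], [], []
    for c, rng in enumerate(_chain_rngs(settings)):
        beta = np.zeros(p)
        u = np.zeros(n)
        sigma2 = prior.sigma2_fixed or float(np.var(yc) * (0.5 + 0.5 * c) + 0.1)
        sigma_u2 = prior.sigma_u2_fixed or float(0.5 * (1 + c))
        r = yc - Xc @ beta - u

        bdraws = np.empty((L_chain, p))
        udraws = np.empty((L_chain, n))
        s2draws = np.empty(L_chain)
        su2draws = np.empty(L_chain)
        kept = 0
        for it in range(settings.n_iter):
            inv_s2 = 1.0 / sigma2
            if p:
                order = rng.permutation(p)
                for j in order:
                    xj = Xc[:, j]
                    bj = beta[j]
                    prec = xtx[j] * inv_s2 + 1.0 / prior.tau2
                    mean = (xj @ r + xtx[j] * bj) * inv_s2 / prec
                    bnew = mean + rng.standard_normal() / np.sqrt(prec)
                    r -= xj * (bnew - bj)
                    beta[j] = bnew

            resid_wo_u = r + u
            u, d = _update_polygenic(rng, resid_wo_u, evals, evecs, sigma2, sigma_u2)
            r = resid_wo_u - u

            if prior.sigma_u2_fixed is None:
                sigma_u2 = _update_sigma_u2(rng, d, evals, prior.a_u, prior.b_u)
            if prior.sigma2_fixed is None:
                sigma2 = _draw_ig(
                    rng, prior.a_sigma + 0.5 * n, prior.b_sigma + 0.5 * float(r @ r)
                )

            if retain[it]:
                bdraws[kept] = beta
                udraws[kept] = u
                s2draws[kept] = sigma2
                su2draws[kept] = sigma_u2
                kept += 1
        beta_out.append(bdraws)
        u_out.append(udraws)
        s2_out.append(s2draws)
        su2_out.append(su2draws)
        chain_out.append(np.full(L_chain, c))

    return PosteriorSamples(
        model_tag="blmm",
        beta_draws=np.vstack(beta_out),
        u_draws=np.vstack(u_out),
        variance_draws={
            "sigma2": np.concatenate(s2_out),
            "sigma_u2": np.concatenate(su2_out),
        },
        chain_ids=np.concatenate(chain_out),
        context=ctx,
        meta={"settings": settings, "prior": prior},
    )


# ---------------------------------------------------------------------------
# Bayesian sparse linear mixed model
# ---------------------------------------------------------------------------

def fit_bslmm(
    X,
    y,
    prior: BslmmPrior | None = None,
    settings: McmcSettings | None = None,
    kinship: np.ndarray | None = None,
) -> PosteriorSamples:
    """MCMC sampler for the BSLMM (point-mass + slab effects over kinship).

    Per iteration: mu Gaussian; each beta_j by a marginalized two-state
    update — the slab density is integrated analytically given the
    residual, giving point-mass-vs-slab odds pi/(1-pi) * BF_j; if
    included, beta_j is drawn from its Gaussian full conditional, else
    set exactly to zero; u in the kinship eigenbasis; sigma_a2, sigma_b2
    inverse-gamma; 1/sigma_eps2 Gamma; pi by random-walk Metropolis on
    log(pi) under its uniform prior (proposal sd adapted during burn-in
    only).  When every beta is excluded, sigma_a2 is refreshed from its
    prior (counted in ``meta["sigma_a2_prior_draws"]``).
    """
    prior = prior or BslmmPrior()
    settings = settings or McmcSettings()
    Xc, y_raw, ctx = _prepare_xy(X, y, center_y=False)
    n, p = Xc.shape
    if p < 1:
        raise ValueError("bslmm requires at least one marker")
    use_u = prior.sigma_b2_fixed is None or prior.sigma_b2_fixed > _VAR_FLOOR
    if use_u or kinship is not None:
        if kinship is not None:
            K = np.asarray(kinship, dtype=float)
        else:
            K = compute_kinship(Xc, denominator=prior.kinship_denominator)
        evals, evecs = kinship_eigh(K)
    else:
        evals = evecs = None
    ctx.X_train_centered = Xc
    ctx.kinship_denominator = prior.kinship_denominator

    sigma_mu2 = prior.sigma_mu2 if prior.sigma_mu2 is not None else float(np.var(y_raw))
    sigma_mu2 = max(sigma_mu2, _VAR_FLOOR)
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    retain = _retain_mask(settings)
    L_chain = int(retain.sum())
    log_pi_lo, log_pi_hi = np.log(1.0 / p), 0.0

    beta_out, gamma_out, mu_out, u_out = [], [], [], []
    sa2_out, sb2_out, se2_out, pi_out, chain_out = [], [], [], [], []
    n_accept = n_propose = n_prior_sa2 = 0
    for c, rng in enumerate(_chain_rngs(settings)):
        beta = np.zeros(p)
        gamma = np.zeros(p, dtype=np.int8)
        mu = float(y_raw.mean()) * (0.5 + 0.5 * c)
        u = np.zeros(n)
        sigma_a2 = prior.sigma_a2_fixed if prior.sigma_a2_fixed is not None else 0.1 * (1 + c)
        sigma_b2 = prior.sigma_b2_fixed if prior.sigma_b2_fixed is not None else 0.5 * (1 + c)
        sigma_e2 = prior.sigma_eps2_fixed or float(np.var(y_raw) * (0.5 + 0.5 * c) + 0.1)
        if prior.pi_fixed is not None:
            log_pi = np.log(prior.pi_fixed) if prior.pi_fixed > 0 else -np.inf
        else:
            log_pi = np.log(0.5 * (1.0 / p) ** (c / max(settings.n_chains - 1, 1)))
            log_pi = float(np.clip(log_pi, log_pi_lo, log_pi_hi - 1e-9))
        prop_sd = prior.pi_proposal_sd
        r = y_raw - mu - Xc @ beta - u

        bdraws = np.empty((L_chain, p))
        gdraws = np.empty((L_chain, p), dtype=np.int8)
        mudraws = np.empty(L_chain)
        udraws = np.empty((L_chain, n))
        sa2draws = np.empty(L_chain)
        sb2draws = np.empty(L_chain)
        se2draws = np.empty(L_chain)
        pidraws = np.empty(L_chain)
        kept = 0
        for it in range(settings.n_iter):
            inv_se2 = 1.0 / sigma_e2
            # intercept
            prec_mu = n * inv_se2 + 1.0 / sigma_mu2
            mean_mu = float(np.sum(r + mu)) * inv_se2 / prec_mu
            mu_new = mean_mu + rng.standard_normal() / np.sqrt(prec_mu)
            r -= mu_new - mu
            mu = mu_new

            # marginalized two-state beta updates
            if np.isinf(log_pi) and log_pi < 0:
                log_odds_base = -np.inf
            elif log_pi >= 0.0:
                log_odds_base = np.inf
            else:
                log_odds_base = log_pi - np.log1p(-np.exp(log_pi))
            order = rng.permutation(p)
            for j in order:
                xj = Xc[:, j]
                bj = beta[j]
                s = xtx[j] * inv_se2 + 1.0 / sigma_a2
                m = (xj @ r + xtx[j] * bj) * inv_se2 / s
                if np.isinf(log_odds_base):
                    include = log_odds_base > 0
                else:
                    log_bf = -0.5 * np.log(sigma_a2 * s) + 0.5 * m * m * s
                    lo = log_odds_base + log_bf
                    include = rng.random() < 1.0 / (1.0 + np.exp(-np.clip(lo, -700, 700)))
                bnew = (m + rng.standard_normal() / np.sqrt(s)) if include else 0.0
                gamma[j] = 1 if include else 0
                if bnew != bj:
                    r -= xj * (bnew - bj)
                beta[j] = bnew

            S = int(gamma.sum())
            if prior.sigma_a2_fixed is not None:
                pass
            elif S > 0:
                sigma_a2 = _draw_ig(
                    rng,
                    prior.alpha_a + 0.5 * S,
                    prior.gamma_a + 0.5 * float(np.sum(beta[gamma == 1] ** 2)),
                )
            else:
                sigma_a2 = _draw_ig(rng, prior.alpha_a, prior.gamma_a)
                n_prior_sa2 += 1

            if use_u:
                resid_wo_u = r + u
                u, d = _update_polygenic(rng, resid_wo_u, evals, evecs, sigma_e2, sigma_b2)
                r = resid_wo_u - u
                if prior.sigma_b2_fixed is None:
                    sigma_b2 = _update_sigma_u2(rng, d, evals, prior.alpha_b, prior.gamma_b)

            if prior.sigma_eps2_fixed is None:
                prec_e = rng.gamma(
                    prior.alpha_eps + 0.5 * n, 1.0 / (prior.gamma_eps + 0.5 * float(r @ r))
                )
                sigma_e2 = 1.0 / max(prec_e, _VAR_FLOOR)

            if prior.pi_fixed is None:
                # random-walk Metropolis on log pi, uniform prior on its support
                prop = log_pi + prop_sd * rng.standard_normal()
                n_propose += 1
                if log_pi_lo <= prop < log_pi_hi:
                    def _log_target(t: float) -> float:
                        return S * t + (p - S) * np.log1p(-np.exp(t))
                    if np.log(rng.random() + 1e-300) < _log_target(prop) - _log_target(log_pi):
                        log_pi = prop
                        n_accept += 1
                if it < settings.burn_in and it % 100 == 99:
                    rate = n_accept / max(n_propose, 1)
                    prop_sd *= 1.1 if rate > 0.5 else 0.9
                    prop_sd = float(np.clip(prop_sd, 0.01, 2.0))

            if retain[it]:
                bdraws[kept] = beta
                gdraws[kept] = gamma
                mudraws[kept] = mu
                udraws[kept] = u
                sa2draws[kept] = sigma_a2
                sb2draws[kept] = sigma_b2
                se2draws[kept] = sigma_e2
                pidraws[kept] = np.exp(log_pi)
                kept += 1
        beta_out.append(bdraws)
        gamma_out.append(gdraws)
        mu_out.append(mudraws)
        u_out.append(udraws)
        sa2_out.append(sa2draws)
        sb2_out.append(sb2draws)
        se2_out.append(se2draws)
        pi_out.append(pidraws)
        chain_out.append(np.full(L_chain, c))

    return PosteriorSamples(
        model_tag="bslmm",
        beta_draws=np.vstack(beta_out),
        gamma_draws=np.vstack(gamma_out),
        mu_draws=np.concatenate(mu_out),
        u_draws=np.vstack(u_out),
        variance_draws={
            "sigma_eps2": np.concatenate(se2_out),
            "sigma_a2": np.concatenate(sa2_out),
            "sigma_b2": np.concatenate(sb2_out),
            "pi": np.concatenate(pi_out),
        },
        chain_ids=np.concatenate(chain_out),
        context=ctx,
        meta={
            "settings": settings,
            "prior": prior,
            "pi_acceptance": n_accept / max(n_propose, 1),
            "sigma_a2_prior_draws": n_prior_sa2,
        },
    )
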