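"""Posterior-predictive simulation for new individuals.

For each retained posterior draw the predictive response is simulated as
y* = mu + X* beta + u* + eps with eps ~ N(0, sigma_eps2): the Monte Carlo
average of these draws is the point prediction, and empirical quantiles
give the predictive interval (5th/95th percentiles at the default 90%
level).  For models with a polygenic term, u* for unseen individuals is
drawn from its Gaussian conditional given the training-individual draws
through the cross-kinship (generalized inverse with jitter); a beta-only
mode skips that term for comparison.
"""

from __future__ import annotations

import numpy as np

from .kinship import compute_kinship
from .types import GenotypeMatrix, PosteriorSamples, PredictionResult

__all__ = ["posterior_predict", "point_predict_frequentist"]


def _align_new(X_new, marker_ids: list[str]):
    """Return (raw dosage array, sample ids) aligned to the training markers."""
    if isinstance(X_new, GenotypeMatrix):
        if list(X_new.marker_ids) != list(marker_ids):
            missing = sorted(set(marker_ids) - set(X_new.marker_ids))
            extra = sorted(set(X_new.marker_ids) - set(marker_ids))
            if missing or extra:
                raise ValueError(
                    f"marker mismatch: missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
                    f"extra {extra[:5]}{'...' if len(extra) > 5 else ''}"
                )
            # same set, different order: realign
            idx = [X_new.marker_ids.index(m) for m in marker_ids]
            return X_new.dosages[:, idx].astype(float), list(X_new.sample_ids)
        return X_new.dosages.astype(float), list(X_new.sample_ids)
    X = np.asarray(X_new, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(marker_ids):
        raise ValueError(
            f"X_new must have {len(marker_ids)} columns, got shape {X.shape}"
        )
    return X, None


def posterior_predict(
    samples: PosteriorSamples,
    X_new,
    level: float = 0.90,
    include_polygenic: bool = True,
    seed: int = 0,
) -> PredictionResult:
    """Simulate the posterior-predictive distribution at new genotypes.

    ``level`` sets the empirical-quantile interval (0.90 gives the
    5th–95th percentile band).  Predictive noise and, where applicable,
    test-individual polygenic values are drawn with a dedicated ``seed``
    so predictions are reproducible given the posterior draws.
    """
    if not (0 < level < 1):
        raise ValueError("interval level must be in (0, 1)")
    ctx = samples.context
    if ctx is None:
        raise ValueError("samples carry no training context; cannot predict")
    X_raw, sample_ids = _align_new(X_new, ctx.marker_ids)
    Xc = X_raw - ctx.col_means
    if ctx.col_sds is not None:
        Xc = Xc / np.where(ctx.col_sds > 0, ctx.col_sds, 1.0)
    m = Xc.shape[0]
    L = samples.n_draws
    # independent substreams so toggling the polygenic term leaves the
    # predictive-noise draws unchanged
    ss_poly, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_poly)
    rng_noise = np.random.default_rng(ss_noise)

    draws = samples.beta_draws @ Xc.T  # L x m
    if samples.mu_draws is not None:
        draws = draws + samples.mu_draws[:, None]
    draws = draws + ctx.y_offset

    if include_polygenic and samples.u_draws is not None:
        draws = draws + _polygenic_for_new(samples, Xc, rng)

    vd = samples.variance_draws
    noise_var = vd.get("sigma_eps2", vd.get("sigma2"))
    if noise_var is None:
        raise ValueError("no residual-variance draws found")
    draws = draws + rng_noise.standard_normal((L, m)) * np.sqrt(noise_var)[:, None]

    point = draws.mean(axis=0)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return PredictionResult(
        draws=draws,
        point=point,
        lower=lower,
        upper=upper,
        interval_level=level,
        model_tag=samples.model_tag,
        sample_ids=sample_ids,
    )


def _polygenic_for_new(samples: PosteriorSamples, Xc_new: np.ndarray, rng) -> np.ndarray:
    """Conditional polygenic draws u* | u^(l) for the test individuals.

    Builds the joint kinship of train+test centered dosages, then for each
    posterior draw samples from N(K21 K11^- u, K22 - K21 K11^- K12); the
    train block is inverted generalized (pinv with jitter) since marker
    kinships are rank-deficient.  The variance-component draw scales the
    Schur complement per iteration.
    """
    ctx = samples.context
    X_train = ctx.X_train_centered
    if X_train is None:
        raise ValueError("training genotypes unavailable for cross-kinship")
    n = X_train.shape[0]
    stacked = np.vstack([X_train, Xc_new])
    # stacked rows are centered w.r.t. training means; kinship on that scale
    denom = n if ctx.kinship_denominator == "n" else max(X_train.shape[1], 1)
    K = stacked @ stacked.T / denom
    K11 = K[:n, :n]
    K21 = K[n:, :n]
    K22 = K[n:, n:]
    jitter = 1e-8 * (np.trace(K11) / n + 1.0)
    K11_inv = np.linalg.pinv(K11 + jitter * np.eye(n), hermitian=True)
    A = K21 @ K11_inv                      # m x n projection
    cond_cov = K22 - A @ K21.T
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    evals, evecs = np.linalg.eigh(cond_cov)
    evals = np.clip(evals, 0.0, None)
    C = evecs * np.sqrt(evals)             # cov^(1/2), unit variance scale

    vd = samples.variance_draws
    var_u = vd.get("sigma_b2", vd.get("sigma_u2"))
    L, m = samples.n_draws, Xc_new.shape[0]
    means = samples.u_draws @ A.T          # L x m
    z = rng.standard_normal((L, m))
    if var_u is None:
        scale = np.ones(L)
    else:
        scale = np.sqrt(var_u)
    # cond_cov was built on the unscaled kinship; u ~ N(0, s2 K) scales it by s2
    return means + (z @ C.T) * scale[:, None]


def point_predict_frequentist(fit, X_new) -> np.ndarray:
    """Linear predictor of a frequentist baseline at new dosages.

    Replays the training-time centering: prediction = intercept +
    (X_new - training column means) @ coefficients.
    """
    X_raw, _ = _align_new(X_new, fit.marker_ids)
    if len(fit.coefficients) != X_raw.shape[1]:
        raise ValueError("coefficient length does not match marker count")
    Xc = X_raw - fit.col_means
    return fit.intercept + Xc @ fit.coefficients
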