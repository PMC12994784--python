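"""Phenotype normalization and genotype centering.

Quantitative traits entering the Bayesian regressions are assumed
approximately Gaussian; skewed traits are mapped onto normal quantiles by
ordered quantile normalization (OQN), a rank-based inverse-normal
transform.  The OQN map is fitted on training data only and applied to
held-out data by interpolation, so cross-validation stays leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import PhenotypeVector

__all__ = [
    "NormalityReport",
    "OqnMap",
    "test_normality",
    "oqn_fit_transform",
    "oqn_apply",
    "center_genotypes",
]

_MIN_N = 8
_SHAPIRO_CAP = 5000  # subsample above this (fixed seed) to keep W calibrated


@dataclass
class NormalityReport:
    test_name: str
    statistic: float
    p_value: float
    decision_alpha: float
    is_normal: bool


@dataclass
class OqnMap:
    """Fitted ordered-quantile map: sorted training values -> normal scores."""

    sorted_training_values: np.ndarray
    normal_scores: np.ndarray
    offset_constant: float = 0.5


def _as_values(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def test_normality(
    y, alpha: float = 0.05, method: str = "shapiro"
) -> NormalityReport:
    """Omnibus normality test (Shapiro–Wilk default, Anderson–Darling option).

    Shapiro–Wilk is computed on a fixed-seed subsample when n exceeds the
    conventional cap, since the test statistic is miscalibrated at very
    large n.  Anderson–Darling p-values use the Stephens case-3
    approximation as implemented in scipy's ``anderson`` critical values,
    via ``normal_ad``-style interpolation.
    """
    values = _as_values(y)
    n = values.shape[0]
    if n < _MIN_N:
        raise ValueError(f"normality test requires n >= {_MIN_N}, got {n}")
    if np.ptp(values) == 0:
        raise ValueError("constant phenotype: normality test undefined")
    if method == "shapiro":
        sample = values
        if n > _SHAPIRO_CAP:
            idx = np.random.default_rng(0).choice(n, _SHAPIRO_CAP, replace=False)
            sample = values[idx]
        stat, p = stats.shapiro(sample)
        name = "shapiro_wilk"
    elif method == "anderson":
        from statsmodels.stats.diagnostic import normal_ad

        stat, p = normal_ad(values)
        name = "anderson_darling"
    else:
        raise ValueError(f"unknown normality test {method!r}")
    return NormalityReport(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        decision_alpha=alpha,
        is_normal=bool(p >= alpha),
    )


def oqn_fit_transform(y, offset_constant: float = 0.5):
    """Map a sample onto standard-normal quantiles of its offset ranks.

    output_i = Phi^{-1}((rank_i - c) / (n - 2c + 1)) with c the offset
    constant (0.5, the rankit convention); ties share averaged ranks.
    Returns the transformed phenotype and the fitted :class:`OqnMap`
    (unique sorted input values paired with their normal scores) for
    applying the same map to new data.
    """
    values = _as_values(y)
    n = values.shape[0]
    if n < _MIN_N:
        raise ValueError(f"OQN requires n >= {_MIN_N}, got {n}")
    if np.ptp(values) == 0:
        raise ValueError("all-tied phenotype: OQN undefined")
    c = offset_constant
    ranks = stats.rankdata(values, method="average")
    scores = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))

    # knots: unique input values with their (tie-shared) scores
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    sorted_scores = scores[order]
    uniq_vals, first_idx = np.unique(sorted_vals, return_index=True)
    uniq_scores = sorted_scores[first_idx]
    oqn_map = OqnMap(uniq_vals, uniq_scores, offset_constant=c)

    if isinstance(y, PhenotypeVector):
        out = PhenotypeVector(scores, trait_name=y.trait_name, transform_applied="oqn")
    else:
        out = PhenotypeVector(scores, transform_applied="oqn")
    return out, oqn_map


def oqn_apply(oqn_map: OqnMap, new_values) -> np.ndarray:
    """Transform new values with a fitted OQN map.

    Piecewise-linear interpolation between training knots; values beyond
    the training range are extrapolated linearly from the two nearest
    knots on that side.
    """
    xk = np.asarray(oqn_map.sorted_training_values, dtype=float)
    yk = np.asarray(oqn_map.normal_scores, dtype=float)
    if xk.size == 0:
        raise ValueError("empty OQN map")
    v = _as_values(new_values)
    if xk.size == 1:
        return np.full_like(v, yk[0])
    out = np.interp(v, xk, yk)
    lo_slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
    hi_slope = (yk[-1] - yk[-2]) / (xk[-1] - xk[-2])
    below = v < xk[0]
    above = v > xk[-1]
    out[below] = yk[0] + lo_slope * (v[below] - xk[0])
    out[above] = yk[-1] + hi_slope * (v[above] - xk[-1])
    return out


def center_genotypes(X, scale: bool = False):
    """Column-center (optionally standardize) a dosage matrix.

    Returns ``(X_centered, col_means, col_sds, monomorphic)``;
    ``col_sds`` is None when ``scale`` is False.  Monomorphic (constant)
    columns are left at zero and flagged rather than raising.
    """
    from .types import GenotypeMatrix

    if isinstance(X, GenotypeMatrix):
        X = X.dosages
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    Xc = X - means
    monomorphic = np.ptp(X, axis=0) == 0
    sds = None
    if scale:
        sds = X.std(axis=0)
        safe = np.where(sds > 0, sds, 1.0)
        Xc = Xc / safe
        sds = np.where(monomorphic, 1.0, sds)
    return Xc, means, sds, monomorphic
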