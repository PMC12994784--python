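"""Frequentist comparators: OLS, ridge and LASSO regression.

OLS at p > n returns the minimum-norm least-squares (pseudoinverse)
solution, which interpolates the training data.  Ridge is solved in
closed form through the SVD (all penalties in one decomposition); LASSO
uses scikit-learn's coordinate descent on internally standardized
predictors, with coefficients reported back on the original dosage
scale.  Penalties are chosen by inner 5-fold cross-validation on the
training fold only, so outer cross-validation stays leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.linear_model import Lasso

from .types import GenotypeMatrix

__all__ = ["PenalizedFit", "fit_ols", "fit_ridge", "fit_lasso"]


@dataclass
class PenalizedFit:
    """A fitted frequentist baseline, coefficients on the dosage scale."""

    method: str                       # ols | ridge | lasso
    intercept: float
    coefficients: np.ndarray
    penalty: float = 0.0
    selection_trace: list = field(default_factory=list)  # (penalty, inner-CV MSE)
    col_means: np.ndarray = None
    marker_ids: list[str] = None


def _prep(X, y):
    if isinstance(X, GenotypeMatrix):
        marker_ids = list(X.marker_ids)
        X = X.dosages
    else:
        X = np.asarray(X)
        marker_ids = [f"m{j}" for j in range(X.shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    col_means = X.mean(axis=0)
    return X - col_means, y - y.mean(), float(y.mean()), col_means, marker_ids


def _inner_folds(n: int, k: int = 5, seed: int = 0):
    idx = np.random.default_rng(seed).permutation(n)
    return np.array_split(idx, k)


def fit_ols(X, y) -> PenalizedFit:
    """Least squares; minimum-norm (pseudoinverse) solution when p >= n."""
    Xc, yc, intercept, col_means, marker_ids = _prep(X, y)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return PenalizedFit(
        method="ols",
        intercept=intercept,
        coefficients=coef,
        penalty=0.0,
        col_means=col_means,
        marker_ids=marker_ids,
    )


def _ridge_path(Xc, yc, penalties):
    """Closed-form ridge coefficients for every penalty via one SVD."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    coefs = []
    for lam in penalties:
        shrink = s / (s**2 + lam)
        coefs.append(Vt.T @ (shrink * uty))
    return coefs


def fit_ridge(X, y, penalty_grid=None, cv_seed: int = 0) -> PenalizedFit:
    """Ridge regression with the penalty picked by inner 5-fold CV."""
    Xc, yc, intercept, col_means, marker_ids = _prep(X, y)
    if penalty_grid is None:
        penalty_grid = np.logspace(-3, 5, 50)
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")
    if np.any(penalty_grid < 0):
        raise ValueError("penalties must be non-negative")

    trace = []
    if penalty_grid.size > 1:
        folds = _inner_folds(len(yc), seed=cv_seed)
        errs = np.zeros(penalty_grid.size)
        for held in folds:
            mask = np.ones(len(yc), dtype=bool)
            mask[held] = False
            coefs = _ridge_path(Xc[mask], yc[mask], penalty_grid)
            for i, coef in enumerate(coefs):
                pred = Xc[held] @ coef
                errs[i] += float(np.mean((yc[held] - pred) ** 2))
        errs /= len(folds)
        trace = list(zip(penalty_grid.tolist(), errs.tolist()))
        best = penalty_grid[int(np.argmin(errs))]
    else:
        best = float(penalty_grid[0])
    coef = _ridge_path(Xc, yc, [best])[0]
    return PenalizedFit(
        method="ridge",
        intercept=intercept,
        coefficients=coef,
        penalty=float(best),
        selection_trace=trace,
        col_means=col_means,
        marker_ids=marker_ids,
    )


def _lasso_solve(Xs, yc, alpha, n):
    if alpha <= 0:
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return coef, None
    model = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000, tol=1e-7)
    model.fit(Xs, yc)
    return model.coef_.copy(), model


def fit_lasso(X, y, penalty_grid=None, cv_seed: int = 0) -> PenalizedFit:
    """LASSO (coordinate descent) with inner 5-fold CV penalty selection.

    Predictors are standardized internally; reported coefficients are
    rescaled to the original dosage scale, exact zeros preserved.  The
    penalty is scikit-learn's ``alpha`` (L1 weight on the 1/(2n) squared
    loss); values above max|X^T y|/n give the all-zero model.
    """
    Xc, yc, intercept, col_means, marker_ids = _prep(X, y)
    n = len(yc)
    sds = Xc.std(axis=0)
    safe_sds = np.where(sds > 0, sds, 1.0)
    Xs = Xc / safe_sds
    if penalty_grid is None:
        alpha_max = float(np.max(np.abs(Xs.T @ yc)) / n) if Xs.size else 1.0
        alpha_max = max(alpha_max, 1e-12)
        penalty_grid = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), 50)
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")

    trace = []
    if penalty_grid.size > 1:
        folds = _inner_folds(n, seed=cv_seed)
        errs = np.zeros(penalty_grid.size)
        for held in folds:
            mask = np.ones(n, dtype=bool)
            mask[held] = False
            for i, alpha in enumerate(penalty_grid):
                coef, _ = _lasso_solve(Xs[mask], yc[mask], alpha, mask.sum())
                pred = Xs[held] @ coef
                errs[i] += float(np.mean((yc[held] - pred) ** 2))
        errs /= len(folds)
        trace = list(zip(penalty_grid.tolist(), errs.tolist()))
        best = float(penalty_grid[int(np.argmin(errs))])
    else:
        best = float(penalty_grid[0])

    coef_std, model = _lasso_solve(Xs, yc, best, n)
    if model is not None and model.n_iter_ >= 50_000:
        raise RuntimeError(
            f"lasso coordinate descent did not converge at alpha={best:.4g} "
            f"(n_iter={model.n_iter_}, dual gap unresolved at tol=1e-7)"
        )
    coef = coef_std / safe_sds  # back to dosage scale; zeros stay exact
    return PenalizedFit(
        method="lasso",
        intercept=intercept,
        coefficients=coef,
        penalty=best,
        selection_trace=trace,
        col_means=col_means,
        marker_ids=marker_ids,
    )
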