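"""Marker-derived kinship (genomic relationship) matrices."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["compute_kinship", "kinship_eigh"]

_CENTER_TOL = 1e-8


def compute_kinship(X_centered: np.ndarray, denominator: str = "n") -> np.ndarray:
    """K = X X^T / denom from a column-centered dosage matrix.

    ``denominator="n"`` (number of individuals) is the default; ``"p"``
    (number of markers, the usual genomic-relationship normalization) is
    available.  The result is symmetric positive semidefinite.  A
    non-centered input is flagged with a warning, not an error.
    """
    X = np.asarray(X_centered, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    col_means = X.mean(axis=0)
    if X.shape[1] and np.abs(col_means).max() > _CENTER_TOL:
        warnings.warn(
            "kinship input does not look column-centered "
            f"(max |column mean| = {np.abs(col_means).max():.3g})",
            stacklevel=2,
        )
    n, p = X.shape
    if denominator == "n":
        denom = n
    elif denominator == "p":
        denom = max(p, 1)
    else:
        raise ValueError("denominator must be 'n' or 'p'")
    K = X @ X.T / denom
    return (K + K.T) / 2.0  # enforce exact symmetry


def kinship_eigh(K: np.ndarray, floor: float = 1e-10):
    """Eigendecomposition of a kinship matrix with tiny-eigenvalue flooring.

    Returns ``(eigvals, eigvecs)`` with eigenvalues clipped at zero below
    ``floor`` (numerical negatives from the PSD product are truncated).
    Fitters call this once per fit and reuse the basis across iterations.
    """
    vals, vecs = np.linalg.eigh(np.asarray(K, dtype=float))
    vals = np.where(vals < floor, 0.0, vals)
    return vals, vecs
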