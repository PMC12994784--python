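"""Core data containers shared across the package.

The containers are deliberately thin: genotypes are a plain dosage matrix
with sample/marker labels, phenotypes a labelled vector, and posterior
output a bundle of draw matrices.  Heavy lifting (sampling, prediction,
evaluation) lives in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "TruthRecord",
    "TrainContext",
    "PosteriorSamples",
    "PredictionResult",
]


@dataclass
class GenotypeMatrix:
    """n x p minor-allele dosage matrix (entries 0/1/2) with labels."""

    dosages: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.marker_ids) != p:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.dosages, (0, 1, 2)))[0]
            raise ValueError(
                f"dosage not in {{0,1,2}} at row {bad[0]}, column {bad[1]}"
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=self.marker_ids
        )


@dataclass
class PhenotypeVector:
    """One trait with provenance of any normalization applied."""

    values: np.ndarray
    trait_name: str = "trait"
    transform_applied: str = "none"  # {"none", "oqn"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TruthRecord:
    """Ground truth stored by the simulator for recovery tests."""

    beta_true: np.ndarray        # sparse marker effects
    gamma_true: np.ndarray       # 0/1 causal indicators
    u_true: np.ndarray           # polygenic values per individual
    sigma_eps2_true: float       # residual variance
    realized_h2: float           # empirical var(Xb + u) / var(y)

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=int)
        self.u_true = np.asarray(self.u_true, dtype=float)
        if np.any((self.gamma_true == 0) & (self.beta_true != 0)):
            raise ValueError("beta_true must be zero wherever gamma_true is zero")


@dataclass
class TrainContext:
    """Training-time state needed to predict for new individuals.

    Stores the centering replayed on test genotypes, the intercept absorbed
    by centering y (models without an explicit mu term), and, for models
    with a polygenic term, the centered training dosages for cross-kinship.
    """

    marker_ids: list[str]
    col_means: np.ndarray
    col_sds: Optional[np.ndarray] = None       # None when not scaled
    y_offset: float = 0.0                      # mean removed from y pre-fit
    X_train_centered: Optional[np.ndarray] = None
    kinship_denominator: str = "n"


@dataclass
class PosteriorSamples:
    """Retained post-burn-in MCMC draws, concatenated across chains."""

    model_tag: str                                # spike_slab|blasso|blmm|bslmm
    beta_draws: np.ndarray                        # L x p
    variance_draws: dict[str, np.ndarray]         # named positive scalar draws
    chain_ids: np.ndarray                         # L chain labels
    gamma_draws: Optional[np.ndarray] = None      # L x p indicators
    mu_draws: Optional[np.ndarray] = None         # L intercept draws
    u_draws: Optional[np.ndarray] = None          # L x n polygenic draws
    context: Optional[TrainContext] = None
    meta: dict = field(default_factory=dict)      # settings, acceptance rates

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def p(self) -> int:
        return self.beta_draws.shape[1]

    def to_frame(self, include_beta: bool = True) -> pd.DataFrame:
        """Draws as a tidy table, one row per retained draw."""
        cols: dict[str, np.ndarray] = {"chain": self.chain_ids}
        if self.mu_draws is not None:
            cols["mu"] = self.mu_draws
        for name, draws in self.variance_draws.items():
            cols[name] = draws
        if include_beta:
            for j in range(self.p):
                cols[f"beta_{j}"] = self.beta_draws[:, j]
        return pd.DataFrame(cols)


@dataclass
class PredictionResult:
    """Posterior-predictive draws and empirical-quantile intervals."""

    draws: np.ndarray            # L x m predictive draws
    point: np.ndarray            # m posterior-predictive means
    lower: np.ndarray            # m lower interval bounds
    upper: np.ndarray            # m upper interval bounds
    interval_level: float
    model_tag: str
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def m(self) -> int:
        return self.point.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or [f"ind{i}" for i in range(self.m)]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "point": self.point,
                "lower": self.lower,
                "upper": self.upper,
                "model_tag": self.model_tag,
                "level": self.interval_level,
            }
        )
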