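"""Cross-validation harness and prediction metrics.

The default protocol is 5-fold cross-validation: each fold trains on 80%
of individuals and predicts the held-out 20%.  All preprocessing that
looks at the phenotype (normality testing, the OQN map) is fitted on the
training fold and applied to the held-out fold, and all metrics are
computed on the modeling (transformed) scale.  Reports carry per-fold
values plus the mean/min/max aggregate per model, with coverage and model
size left blank where they are undefined (OLS/ridge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import baselines, samplers
from .predict import point_predict_frequentist, posterior_predict
from .preprocess import oqn_apply, oqn_fit_transform, test_normality
from .types import GenotypeMatrix, PhenotypeVector, PosteriorSamples, PredictionResult

__all__ = [
    "FoldAssignment",
    "SelectionRule",
    "CvReport",
    "kfold_split",
    "rmse",
    "mae",
    "predictive_coverage",
    "model_size",
    "run_cv",
    "residual_table",
]

BAYES_MODELS = ("spike_slab", "blasso", "blmm", "bslmm")
FREQ_MODELS = ("ols", "ridge", "lasso")


@dataclass
class FoldAssignment:
    """A balanced random partition of n individuals into k folds (1..k)."""

    n: int
    k: int
    fold_of: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class SelectionRule:
    """How 'non-zero effect' is decided per model family.

    Exact-zero counting for the LASSO; PIP > ``pip_threshold`` for the
    indicator models (spike-and-slab, BSLMM); an equal-tailed credible
    interval at ``ci_level`` excluding zero for the Bayesian LASSO.
    """

    pip_threshold: float = 0.5
    ci_level: float = 0.90


def kfold_split(n: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniformly random balanced k-fold partition, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % k + 1
    return FoldAssignment(n=n, k=k, fold_of=fold_of, seed=seed)


def _check_pair(y_true, y_pred):
    a = np.asarray(getattr(y_true, "values", y_true), dtype=float).ravel()
    b = np.asarray(y_pred, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size == 0:
        raise ValueError("empty input")
    return a, b


def rmse(y_true, y_pred) -> float:
    """Root mean squared prediction error."""
    a, b = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute prediction error."""
    a, b = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(a - b)))


def predictive_coverage(y_true, result: PredictionResult) -> float:
    """Fraction of held-out values inside [lower, upper], ends inclusive."""
    a = np.asarray(getattr(y_true, "values", y_true), dtype=float).ravel()
    if a.shape[0] != result.m:
        raise ValueError(f"{a.shape[0]} observations vs {result.m} intervals")
    inside = (a >= result.lower) & (a <= result.upper)
    return float(inside.mean())


def model_size(fit_or_samples, rule: SelectionRule | None = None) -> int:
    """Number of markers with a non-zero effect under the stated rule."""
    rule = rule or SelectionRule()
    obj = fit_or_samples
    if isinstance(obj, baselines.PenalizedFit):
        if obj.method != "lasso":
            raise ValueError(f"model size is not defined for {obj.method}")
        return int(np.sum(obj.coefficients != 0))
    if isinstance(obj, PosteriorSamples):
        if obj.gamma_draws is not None:
            pips = samplers.pip(obj)
            return int(np.sum(pips > rule.pip_threshold))
        if obj.model_tag == "blasso":
            alpha = (1 - rule.ci_level) / 2
            lo = np.quantile(obj.beta_draws, alpha, axis=0)
            hi = np.quantile(obj.beta_draws, 1 - alpha, axis=0)
            return int(np.sum((lo > 0) | (hi < 0)))
        raise ValueError(f"no model-size rule for model {obj.model_tag!r}")
    raise TypeError(f"unsupported object {type(obj).__name__}")


def residual_table(y_true, y_pred, model_tag: str = "") -> pd.DataFrame:
    """Rows of (predicted, residual = observed - predicted) for plotting."""
    a, b = _check_pair(y_true, y_pred)
    return pd.DataFrame(
        {"predicted": b, "residual": a - b, "model_tag": model_tag}
    )


@dataclass
class CvReport:
    """Per-fold metrics and mean/min/max aggregates per model."""

    per_fold: pd.DataFrame
    aggregate: pd.DataFrame
    trait: str
    provenance: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def render(self) -> str:
        """Human-readable table; '-' where a metric is undefined."""
        agg = self.aggregate.copy()
        out = agg.map(lambda v: "-" if pd.isna(v) else f"{v:.4f}")
        return out.to_string()


_BAYES_FITTERS = {
    "spike_slab": (samplers.fit_spike_slab, samplers.SpikeSlabPrior),
    "blasso": (samplers.fit_blasso, samplers.BlassoPrior),
    "blmm": (samplers.fit_blmm, samplers.BlmmPrior),
    "bslmm": (samplers.fit_bslmm, samplers.BslmmPrior),
}


def run_cv(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    models: list[str] | None = None,
    settings: samplers.McmcSettings | None = None,
    level: float = 0.90,
    k: int = 5,
    seed: int = 0,
    normalize: str = "auto",          # "auto" | "always" | "never"
    priors: dict | None = None,
    rule: SelectionRule | None = None,
) -> CvReport:
    """Cross-validated comparison of Bayesian and frequentist models.

    For each fold: the OQN map (if the training trait is non-normal under
    ``normalize="auto"``, or unconditionally under ``"always"``) is fitted
    on the training fold and applied to the held-out fold; every requested
    model is fitted on the training fold and predicts the held-out fold;
    RMSE/MAE (all models), predictive coverage and model size (Bayesian
    models; size also for the LASSO) are recorded.  A model failure marks
    the (fold, model) cell failed and the run continues.
    """
    models = list(models or ["spike_slab", "blasso", "bslmm", "ols", "ridge", "lasso"])
    unknown = [m for m in models if m not in BAYES_MODELS + FREQ_MODELS]
    if unknown:
        raise ValueError(f"unknown model tags {unknown}; known: "
                         f"{BAYES_MODELS + FREQ_MODELS}")
    settings = settings or samplers.McmcSettings()
    priors = priors or {}
    rule = rule or SelectionRule()
    n, p = genotypes.n, genotypes.p
    if phenotype.n != n:
        raise ValueError("phenotype length does not match genotype rows")

    ss = np.random.SeedSequence(seed)
    fold_seed, *model_seeds = [int(s) for s in ss.generate_state(1 + len(models) * k)]
    assignment = kfold_split(n, k=k, seed=fold_seed % (2**31))
    X = genotypes.dosages
    y = phenotype.values

    rows, failures = [], []
    seed_iter = iter(model_seeds)
    for fold in range(1, k + 1):
        tr = assignment.train_indices(fold)
        te = assignment.test_indices(fold)
        y_tr_raw, y_te_raw = y[tr], y[te]

        apply_oqn = normalize == "always"
        if normalize == "auto":
            apply_oqn = not test_normality(y_tr_raw).is_normal
        if apply_oqn:
            pheno_tr, oqn_map = oqn_fit_transform(y_tr_raw)
            y_tr, y_te = pheno_tr.values, oqn_apply(oqn_map, y_te_raw)
        else:
            y_tr, y_te = y_tr_raw, y_te_raw

        X_tr = GenotypeMatrix(
            X[tr],
            [genotypes.sample_ids[i] for i in tr],
            genotypes.marker_ids,
        )
        X_te_arr = X[te].astype(float)

        for model in models:
            mseed = next(seed_iter) % (2**31)
            try:
                row = _fit_one(
                    model, X_tr, y_tr, X_te_arr, y_te, settings, priors,
                    level, rule, mseed,
                )
            except Exception as exc:  # fold marked failed, run continues
                failures.append({"fold": fold, "model": model, "error": str(exc)})
                continue
            row.update({"fold": fold, "model": model, "trait": phenotype.trait_name,
                        "oqn_applied": apply_oqn, "n_test": len(te)})
            rows.append(row)

    per_fold = pd.DataFrame(rows)
    aggregate = _aggregate(per_fold, models)
    return CvReport(
        per_fold=per_fold,
        aggregate=aggregate,
        trait=phenotype.trait_name,
        provenance={
            "seed": seed,
            "k": k,
            "level": level,
            "normalize": normalize,
            "models": models,
            "n": n,
            "p": p,
            "settings": settings,
        },
        failures=failures,
    )


def _fit_one(model, X_tr, y_tr, X_te, y_te, settings, priors, level, rule, mseed):
    import dataclasses as _dc

    if model in BAYES_MODELS:
        fitter, prior_cls = _BAYES_FITTERS[model]
        prior = priors.get(model) or prior_cls()
        fold_settings = _dc.replace(settings, seed=mseed)
        samples = fitter(X_tr, y_tr, prior=prior, settings=fold_settings)
        pred = posterior_predict(samples, X_te, level=level, seed=mseed + 1)
        size = None
        if model != "blmm" or samples.gamma_draws is not None:
            try:
                size = model_size(samples, rule)
            except ValueError:
                size = None
        return {
            "rmse": rmse(y_te, pred.point),
            "mae": mae(y_te, pred.point),
            "coverage": predictive_coverage(y_te, pred),
            "model_size": size,
        }
    if model == "ols":
        fit = baselines.fit_ols(X_tr, y_tr)
    elif model == "ridge":
        fit = baselines.fit_ridge(X_tr, y_tr, cv_seed=mseed)
    else:
        fit = baselines.fit_lasso(X_tr, y_tr, cv_seed=mseed)
    pred_point = point_predict_frequentist(fit, X_te)
    size = model_size(fit, rule) if model == "lasso" else None
    return {
        "rmse": rmse(y_te, pred_point),
        "mae": mae(y_te, pred_point),
        "coverage": None,
        "model_size": size,
    }


def _aggregate(per_fold: pd.DataFrame, models: list[str]) -> pd.DataFrame:
    if per_fold.empty:
        return pd.DataFrame()
    cols = {}
    for metric in ("rmse", "mae", "coverage", "model_size"):
        grouped = per_fold.groupby("model")[metric]
        cols[(metric, "mean")] = grouped.mean()
        cols[(metric, "min")] = grouped.min()
        cols[(metric, "max")] = grouped.max()
    agg = pd.DataFrame(cols)
    agg.columns = pd.MultiIndex.from_tuples(agg.columns, names=["metric", "stat"])
    order = [m for m in models if m in agg.index]
    return agg.loc[order]
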