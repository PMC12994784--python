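"""Cross-validation harness, metrics and reporting identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesgp import (
    GenotypeMatrix,
    McmcSettings,
    PhenotypeVector,
    SelectionRule,
    SimulationConfig,
    fit_lasso,
    kfold_split,
    mae,
    model_size,
    predictive_coverage,
    residual_table,
    rmse,
    run_cv,
    simulate_dataset,
)
from bayesgp.types import PredictionResult


class TestKfold:
    def test_even_split(self):
        folds = kfold_split(10, k=5, seed=0)
        sizes = np.bincount(folds.fold_of)[1:]
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_uneven_split(self):
        sizes = sorted(np.bincount(kfold_split(11, 5, seed=1).fold_of)[1:])
        assert sizes == [2, 2, 2, 2, 3]

    def test_partition_property(self):
        folds = kfold_split(37, 5, seed=2)
        all_idx = np.concatenate([folds.test_indices(f) for f in range(1, 6)])
        assert sorted(all_idx) == list(range(37))
        for f in range(1, 6):
            assert set(folds.test_indices(f)).isdisjoint(folds.train_indices(f))

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5)


class TestMetrics:
    def test_rmse_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mae_hand_value_and_symmetry(self):
        assert mae([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5)
        assert mae([0.0, 0.0], [-3.0, -4.0]) == pytest.approx(3.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_rmse_dominates_mae(self, values, seed):
        rng = np.random.default_rng(seed)
        y = np.asarray(values)
        pred = y + rng.normal(size=y.shape)
        assert rmse(y, pred) >= mae(y, pred) - 1e-12


class TestCoverage:
    def _result(self, lower, upper):
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        mid = (lower + upper) / 2
        return PredictionResult(
            draws=np.vstack([lower, upper]), point=mid, lower=lower,
            upper=upper, interval_level=0.9, model_tag="test",
        )

    def test_wide_intervals_cover_everything(self):
        res = self._result([-1e9, -1e9], [1e9, 1e9])
        assert predictive_coverage([0.0, 123.0], res) == 1.0

    def test_half_covered(self):
        res = self._result([-1.0, -1.0], [1.0, 1.0])
        assert predictive_coverage([0.0, 10.0], res) == 0.5

    def test_boundary_inclusive(self):
        res = self._result([-1.0], [1.0])
        assert predictive_coverage([1.0], res) == 1.0

    def test_mismatch(self):
        with pytest.raises(ValueError):
            predictive_coverage([1.0, 2.0], self._result([0.0], [1.0]))


class TestModelSize:
    def test_lasso_exact_zero_counting(self, toy_regression):
        X, y, _ = toy_regression
        fit = fit_lasso(X, y, penalty_grid=[0.05])
        assert model_size(fit) == int(np.sum(fit.coefficients != 0))

    def test_pip_threshold_rule(self):
        from bayesgp.types import PosteriorSamples

        gam = np.array([[1, 0], [1, 0], [1, 1], [1, 0]], dtype=np.int8)
        samp = PosteriorSamples(
            model_tag="spike_slab", beta_draws=np.zeros((4, 2)),
            variance_draws={}, chain_ids=np.zeros(4), gamma_draws=gam,
        )
        assert model_size(samp, SelectionRule(pip_threshold=0.5)) == 1

    def test_blasso_credible_interval_rule(self):
        from bayesgp.types import PosteriorSamples

        rng = np.random.default_rng(0)
        beta = np.column_stack([
            rng.normal(0, 0.01, 400),    # straddles zero
            rng.normal(3.0, 0.1, 400),   # clearly positive
        ])
        samp = PosteriorSamples(
            model_tag="blasso", beta_draws=beta,
            variance_draws={}, chain_ids=np.zeros(400),
        )
        assert model_size(samp, SelectionRule(ci_level=0.9)) == 1

    def test_incompatible_model(self, toy_regression):
        from bayesgp import fit_ols

        X, y, _ = toy_regression
        with pytest.raises(ValueError, match="not defined"):
            model_size(fit_ols(X, y))


class TestResidualTable:
    def test_perfect_predictions(self):
        table = residual_table([1.0, 2.0], [1.0, 2.0], "m")
        assert np.all(table["residual"] == 0)
        assert len(table) == 2

    def test_mean_identity(self):
        rng = np.random.default_rng(1)
        y, pred = rng.normal(size=20), rng.normal(size=20)
        table = residual_table(y, pred)
        assert table["residual"].mean() == pytest.approx(y.mean() - pred.mean())


@pytest.fixture(scope="module")
def cv_report():
    cfg = SimulationConfig(
        n_individuals=80, n_markers=30, n_causal=3, heritability_target=0.5,
        polygenic_fraction=0.0, ld_block_size=10, seed=13,
    )
    geno, pheno, _ = simulate_dataset(cfg)
    settings = McmcSettings(n_chains=1, n_iter=600, burn_in=200, seed=1)
    report = run_cv(
        geno, pheno, models=["spike_slab", "blasso", "ols", "ridge", "lasso"],
        settings=settings, k=5, seed=99,
    )
    return report


class TestRunCv:
    def test_fold_shapes_and_training_fraction(self, cv_report):
        per_fold = cv_report.per_fold
        assert set(per_fold["fold"]) == {1, 2, 3, 4, 5}
        assert (per_fold["n_test"] == 16).all()  # 80/20 split of n=80
        assert len(per_fold) == 25  # 5 folds x 5 models
        assert not cv_report.failures

    def test_metric_identities_on_all_outputs(self, cv_report):
        per_fold = cv_report.per_fold
        assert (per_fold["rmse"] >= per_fold["mae"] - 1e-12).all()
        cov = per_fold["coverage"].dropna()
        assert cov.between(0, 1).all()
        sizes = per_fold["model_size"].dropna()
        assert sizes.between(0, 30).all()

    def test_aggregate_mean_between_min_and_max(self, cv_report):
        agg = cv_report.aggregate
        for metric in ("rmse", "mae"):
            assert (agg[(metric, "min")] <= agg[(metric, "mean")] + 1e-12).all()
            assert (agg[(metric, "mean")] <= agg[(metric, "max")] + 1e-12).all()

    def test_coverage_blank_for_frequentist_models(self, cv_report):
        per_fold = cv_report.per_fold
        freq = per_fold[per_fold["model"].isin(["ols", "ridge", "lasso"])]
        assert freq["coverage"].isna().all()
        bayes = per_fold[per_fold["model"].isin(["spike_slab", "blasso"])]
        assert bayes["coverage"].notna().all()
        rendered = cv_report.render()
        assert "-" in rendered

    def test_determinism(self):
        cfg = SimulationConfig(
            n_individuals=40, n_markers=10, n_causal=2, ld_block_size=5, seed=3,
        )
        geno, pheno, _ = simulate_dataset(cfg)
        settings = McmcSettings(1, 300, 100, seed=5)
        kwargs = dict(models=["spike_slab", "ridge"], settings=settings, k=4, seed=7)
        a = run_cv(geno, pheno, **kwargs)
        b = run_cv(geno, pheno, **kwargs)
        assert a.per_fold.equals(b.per_fold)

    def test_constant_prediction_rmse_cross_check(self):
        """RMSE of predicting the training mean equals the direct formula."""
        rng = np.random.default_rng(8)
        y = rng.normal(2.0, 1.0, 50)
        const = 2.5
        direct = np.sqrt(np.mean((y - const) ** 2))
        assert rmse(y, np.full(50, const)) == pytest.approx(direct)

    def test_unknown_model_rejected(self, small_panel):
        geno, pheno, _ = small_panel
        with pytest.raises(ValueError, match="unknown model"):
            run_cv(geno, pheno, models=["spike_slab", "gblup"])

    def test_skewed_trait_triggers_oqn(self):
        cfg = SimulationConfig(
            n_individuals=60, n_markers=10, n_causal=2, heritability_target=0.4,
            skew_transform="exponential", ld_block_size=5, seed=17,
        )
        geno, pheno, _ = simulate_dataset(cfg)
        report = run_cv(
            geno, pheno, models=["ridge"], k=3, seed=2, normalize="auto",
        )
        assert report.per_fold["oqn_applied"].all()
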