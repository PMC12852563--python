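import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enpkit.boost import BoostConfig, EnsembleModel
from enpkit.data import FormulationError
from enpkit.evaluate import (
    ablation,
    compute_metrics,
    default_baselines,
    mccv,
    residual_analysis,
    roc_accuracy,
)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2, 3])
        m = compute_metrics(y, y)
        assert m.mae == m.mse == m.rmse == 0
        assert m.eq10 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = compute_metrics(np.array([3.0, 4.0]), np.array([0.0, 0.0]))
        assert m.mae == pytest.approx(3.5)
        assert m.mse == pytest.approx(12.5)
        assert m.rmse == pytest.approx(np.sqrt(12.5))

    def test_affine_prediction_gives_unit_correlation(self):
        y = np.array([1.0, 2, 5, 9])
        m = compute_metrics(y, 2.5 * y + 3)
        assert m.eq10 == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        m = compute_metrics(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert m.degenerate and np.isnan(m.eq10)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    def test_metric_identities(self, y, seed):
        y = np.asarray(y)
        pred = y + np.random.default_rng(seed).normal(0, 1, len(y))
        m = compute_metrics(y, pred)
        assert m.rmse**2 == pytest.approx(m.mse, abs=1e-10)
        assert m.mae <= m.rmse + 1e-12
        if not m.degenerate:
            assert -1 - 1e-12 <= m.eq10 <= 1 + 1e-12


class TestResiduals:
    def test_symmetric_residuals_unbiased(self):
        rep = residual_analysis(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))
        assert rep.mean == 0 and rep.unbiased

    def test_all_positive_residuals_flagged_biased(self):
        y = np.arange(100, dtype=float)
        rep = residual_analysis(y + 1.0, y)  # every residual +1
        assert not rep.unbiased
        assert rep.sign_test_p < 1e-10

    def test_default_run_residuals_unbiased(self, desk_predictions):
        obs, pred, _ = desk_predictions
        for j in range(3):
            assert residual_analysis(obs[:, j], pred[:, j]).unbiased


class TestROC:
    def test_perfect_score_orders_classes(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 200)
        pred = y + rng.normal(0, 0.3, 200)
        score = -np.abs(y - pred)
        _, _, auc = roc_accuracy(y, pred, score)
        assert auc == pytest.approx(1.0)

    def test_random_score_is_chance_level(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 10000)
        pred = y + rng.normal(0, 0.3, 10000)
        _, _, auc = roc_accuracy(y, pred, rng.normal(0, 1, 10000))
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_four_point_rank_oracle(self):
        y = np.zeros(4)
        pred = np.array([0.1, 0.2, 5.0, 6.0])  # two accurate, two not
        score = np.array([4.0, 3.0, 2.0, 1.0])
        _, _, auc = roc_accuracy(y, pred, score, tau=1.0)
        assert auc == 1.0

    def test_single_class_error_names_tau(self):
        y = np.zeros(10)
        with pytest.raises(FormulationError, match="tau"):
            roc_accuracy(y, y, np.arange(10.0), tau=5.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 500)
        pred = y + rng.normal(0, 0.5, 500)
        score = -np.abs(y - pred) + rng.normal(0, 0.2, 500)
        _, _, a1 = roc_accuracy(y, pred, score)
        _, _, a2 = roc_accuracy(y, pred, np.exp(3 * score) + 7)
        assert a1 == pytest.approx(a2, abs=1e-12)


class _MeanModel:
    def fit(self, train):
        self.mean = train.cqas().mean(axis=0)
        return self

    def predict(self, comps):
        return np.tile(self.mean, (len(comps), 1))


class TestMCCV:
    def test_epsilon_is_mean_of_iterations(self, desk_dataset):
        rep = mccv(desk_dataset, _MeanModel, iterations=3, seed=4)
        assert rep.iterations == 3
        assert rep.epsilon_mean == pytest.approx(rep.epsilons.mean())

    def test_mean_model_matches_analytic_error(self, desk_dataset):
        sub = desk_dataset.subset(np.arange(100))
        rep = mccv(sub, _MeanModel, iterations=2, seed=1, stratify_on="size_nm")
        # a mean predictor's blind RMSE approximates the population std
        pop_sd = desk_dataset.cqas()[:100].std(axis=0)
        for j in range(3):
            assert rep.rmse.iloc[:, j].mean() == pytest.approx(pop_sd[j], rel=0.35)

    def test_single_iteration_equals_single_split(self, desk_dataset):
        from enpkit.data import split_dataset

        seed = 6
        rep = mccv(desk_dataset, _MeanModel, iterations=1, seed=seed)
        inner_seed = int(np.random.default_rng(seed).integers(2**31 - 1, size=1)[0])
        train, blind = split_dataset(desk_dataset, 0.7, seed=inner_seed, stratify_on="size_nm")
        pred = _MeanModel().fit(train).predict(blind.compositions())
        rmse = np.sqrt(np.mean((pred - blind.cqas()) ** 2, axis=0))
        assert np.allclose(rep.rmse.iloc[0].to_numpy(), rmse)

    def test_stability_at_low_noise(self, desk_dataset):
        factory = lambda: EnsembleModel(BoostConfig(epochs=3, iterations_per_epoch=40, seed=0))
        rep = mccv(desk_dataset, factory, iterations=3, seed=2)
        assert rep.eq10.to_numpy().std(axis=0).max() < 0.05


class TestAblation:
    def test_linear_truth_mlr_is_optimal(self):
        rng = np.random.default_rng(3)
        comps = rng.dirichlet(np.ones(5) * 10, size=400) * 100
        size = 120 - 1.0 * (comps[:, 2] - 18)  # exactly linear, no noise
        cqas = np.column_stack([size, np.full(400, 0.15) + 0.001 * comps[:, 0], -35 - 0.2 * comps[:, 4]])
        from enpkit.data import FormulationDataset

        ds = FormulationDataset.from_arrays(comps, cqas)
        factory = lambda: EnsembleModel(BoostConfig(epochs=2, iterations_per_epoch=25, seed=1))
        table = ablation(ds, factory, seed=0)
        mlr = table[(table.method == "MLR")].set_index("cqa")["rmse"]
        assert (mlr < 1e-8).all()

    def test_determinism(self, desk_dataset):
        sub = desk_dataset.subset(np.arange(400))
        factory = lambda: EnsembleModel(BoostConfig(epochs=2, iterations_per_epoch=20, seed=3))
        baselines = {"MLR": default_baselines(0)["MLR"]}
        t1 = ablation(sub, factory, baselines=baselines, seed=5)
        t2 = ablation(sub, factory, baselines=baselines, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_failing_baseline_is_skipped(self, desk_dataset):
        class Broken:
            def fit(self, train):
                raise RuntimeError("boom")

        sub = desk_dataset.subset(np.arange(300))
        factory = lambda: EnsembleModel(BoostConfig(epochs=1, iterations_per_epoch=10, seed=0))
        table = ablation(sub, factory, baselines={"broken": Broken}, seed=0)
        broken_rows = table[table.method == "broken"]
        assert broken_rows["skipped"].all()
        assert not table[table.method == "hybrid"]["skipped"].any()
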