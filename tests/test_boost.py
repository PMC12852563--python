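import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enpkit.boost import (
    BoostConfig,
    EnsembleModel,
    allocate_stage_weights,
    extract_feature_equations,
)
from enpkit.cohort import ground_truth_cqa_array
from enpkit.data import CQAS, FormulationDataset, FormulationError


def _labeled(comps, cqas):
    return FormulationDataset.from_arrays(comps, cqas)


def _random_comps(n, seed=0):
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(5) * 10, size=n) * 100


class TestStageWeights:
    def test_direct_substitution(self):
        assert np.allclose(allocate_stage_weights([0.2, 0.5, 0.8]), [0, 0.5, 1])

    def test_minimum_stage_gets_zero(self):
        w = allocate_stage_weights([0.9, 0.1, 0.4])
        assert w[np.argmin([0.9, 0.1, 0.4])] == 0

    def test_all_equal_convention(self):
        assert np.allclose(allocate_stage_weights([0.3, 0.3, 0.3]), 0)

    @given(st.lists(st.floats(0.001, 100), min_size=1, max_size=30))
    def test_normalized_range(self, rmses):
        w = allocate_stage_weights(rmses)
        assert np.all(w >= 0) and np.all(w <= 1)


class TestFit:
    def test_constant_target_yields_constant_model(self):
        comps = _random_comps(50)
        cqas = np.column_stack([np.full(50, 120.0), np.full(50, 0.15), np.full(50, -35.0)])
        model = EnsembleModel(BoostConfig(epochs=1, iterations_per_epoch=2)).fit(_labeled(comps, cqas))
        pred = model.predict(_random_comps(10, seed=9))
        assert np.allclose(pred, [120.0, 0.15, -35.0])
        assert all(e.constant for e in model.ensembles.values())

    def test_memorizing_config_fits_exactly(self):
        # one full-depth tree at learning rate 1 memorizes a 4-point step function
        comps = _random_comps(4, seed=3)
        y = np.array([100.0, 110.0, 130.0, 140.0])
        cqas = np.column_stack([y, [0.1, 0.2, 0.1, 0.2], [-30.0, -40, -30, -40]])
        cfg = BoostConfig(leaf_size=1, learning_rate=1.0, epochs=1, iterations_per_epoch=1)
        model = EnsembleModel(cfg).fit(_labeled(comps, cqas))
        assert np.allclose(model.predict(comps), cqas, atol=1e-10)

    def test_untrained_model_errors(self):
        with pytest.raises(FormulationError):
            EnsembleModel().predict(_random_comps(3))

    def test_monotone_training_rmse_inverted_mode(self, desk_model):
        for ens in desk_model.ensembles.values():
            trace = np.asarray(ens.rmse_trace)
            assert np.all(np.diff(trace) <= 1e-8 * trace[:-1])

    def test_reconstruction_identity(self, desk_model):
        comps = _random_comps(100, seed=12)
        X01 = comps / 100.0
        pred = desk_model.predict(comps)
        for j, name in enumerate(CQAS):
            ens = desk_model.ensembles[name]
            manual = np.full(len(comps), ens.f0)
            for stage in ens.stages:
                manual += stage.applied_multiplier * stage.tree.predict(X01)
            assert np.allclose(pred[:, j], manual, atol=1e-9)

    def test_removing_all_stages_leaves_training_mean(self, desk_model, desk_split):
        train, _ = desk_split
        for j, name in enumerate(CQAS):
            assert desk_model.ensembles[name].f0 == pytest.approx(train.cqas()[:, j].mean())

    def test_beats_mean_and_single_tree(self, desk_model, desk_split):
        from sklearn.tree import DecisionTreeRegressor

        train, blind = desk_split
        pred = desk_model.predict(blind.compositions())
        obs = blind.cqas()
        for j in range(3):
            hybrid_rmse = np.sqrt(np.mean((pred[:, j] - obs[:, j]) ** 2))
            mean_rmse = np.std(obs[:, j])
            tree = DecisionTreeRegressor(min_samples_leaf=8, random_state=0)
            tree.fit(train.compositions() / 100, train.cqas()[:, j])
            tree_rmse = np.sqrt(np.mean((tree.predict(blind.compositions() / 100) - obs[:, j]) ** 2))
            assert hybrid_rmse < mean_rmse
            assert hybrid_rmse < tree_rmse


class TestOracleEquivalence:
    def test_degenerate_config_matches_reference_boosting(self):
        """One epoch, uniform weights == plain least-squares gradient boosting."""
        from sklearn.ensemble import GradientBoostingRegressor

        rng = np.random.default_rng(0)
        comps = rng.dirichlet(np.ones(5), size=50) * 100
        y = 120 + 3 * comps[:, 2] + rng.normal(0, 1, 50)
        cqas = np.column_stack([y, np.full(50, 0.15), np.full(50, -35.0)])
        cfg = BoostConfig(
            leaf_size=8, learning_rate=0.1, epochs=1, iterations_per_epoch=20,
            weight_mode="uniform", seed=0,
        )
        model = EnsembleModel(cfg).fit(_labeled(comps, cqas))
        mine = model.predict(comps)[:, 0]
        ref = GradientBoostingRegressor(
            n_estimators=20, learning_rate=0.1, min_samples_leaf=8,
            max_depth=None, random_state=0,
        ).fit(comps / 100.0, y).predict(comps / 100.0)
        assert np.max(np.abs(mine - ref)) <= 1e-8


class TestFeatureEquations:
    def test_single_feature_truth_concentrates_importance(self):
        comps = _random_comps(400, seed=5)
        y = 120 - 2.0 * comps[:, 2]  # only pc matters
        cqas = np.column_stack([y, np.full(400, 0.15), np.full(400, -35.0)])
        model = EnsembleModel(BoostConfig(epochs=3, iterations_per_epoch=30, seed=1)).fit(
            _labeled(comps, cqas)
        )
        eq = extract_feature_equations(model)["size_nm"]
        assert eq.importances[2] > 0.95
        assert eq.importances.sum() == pytest.approx(1.0)
        assert eq.partial_effects[2] < 0

    def test_constant_model_degenerate(self):
        comps = _random_comps(40, seed=6)
        cqas = np.column_stack([np.full(40, 120.0), np.full(40, 0.15), np.full(40, -35.0)])
        model = EnsembleModel(BoostConfig(epochs=1, iterations_per_epoch=1)).fit(_labeled(comps, cqas))
        eqs = extract_feature_equations(model)
        assert all(eq.degenerate for eq in eqs.values())

    def test_pc_partial_effect_negative_for_all_cqas(self, desk_model):
        eqs = extract_feature_equations(desk_model)
        for name in CQAS:
            assert eqs[name].partial_effects[2] < 0  # pc is feature index 2


class TestPersistence:
    def test_checkpoint_round_trip(self, desk_model, tmp_path):
        path = tmp_path / "model.json"
        desk_model.save(path)
        back = EnsembleModel.load(path)
        comps = _random_comps(50, seed=7)
        assert np.allclose(desk_model.predict(comps), back.predict(comps), atol=1e-12)

    def test_spread_available_after_reload(self, desk_model, tmp_path):
        path = tmp_path / "model.json"
        desk_model.save(path)
        back = EnsembleModel.load(path)
        comps = _random_comps(5, seed=8)
        assert np.allclose(
            desk_model.stage_prediction_spread(comps),
            back.stage_prediction_spread(comps),
            atol=1e-12,
        )
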