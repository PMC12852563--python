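import numpy as np
import pytest

from enpkit.data import FormulationError
from enpkit.ranking import (
    DEFAULT_PROFILES,
    cma_cqa_correlation,
    identity_line_distance,
    rank_for_profile,
    rerank_by_loss_weights,
    select_top_candidates,
)


class TestIdentityLineDistance:
    def test_on_line_is_zero(self):
        assert identity_line_distance(3.7, 3.7) == 0

    def test_unit_offset(self):
        assert identity_line_distance(1.0, 0.0) == pytest.approx(1 / np.sqrt(2))

    def test_symmetric(self):
        assert identity_line_distance(2.0, 5.0) == identity_line_distance(5.0, 2.0)


def _blind_fixture(n=20, seed=0):
    rng = np.random.default_rng(seed)
    comps = rng.dirichlet(np.ones(5) * 10, size=n) * 100
    obs = np.column_stack([
        rng.normal(120, 8, n), rng.normal(0.15, 0.03, n).clip(0.02), rng.normal(-35, 3, n)
    ])
    pred = obs + rng.normal(0, [2.0, 0.01, 1.0], size=(n, 3))
    return obs, pred, comps


class TestSelectTopCandidates:
    def test_k_equals_n_returns_all_sorted(self):
        obs, pred, comps = _blind_fixture()
        cands = select_top_candidates(obs, pred, comps, k=len(obs))
        assert len(cands) == len(obs)
        d = [c.pooled_distance for c in cands]
        assert d == sorted(d)
        assert sorted(c.rank for c in cands) == list(range(1, len(obs) + 1))

    def test_zero_residual_record_ranks_first(self):
        obs, pred, comps = _blind_fixture()
        pred[7] = obs[7]
        cands = select_top_candidates(obs, pred, comps, k=5)
        assert cands[0].index == 7 and cands[0].pooled_distance == 0

    def test_hand_computed_pooled_distances(self):
        # 5 records, unstandardized pooling: sqrt(sum (|e|/sqrt2)^2)
        obs = np.zeros((5, 3))
        errs = np.array([
            [1.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
            [1.0, 1.0, 1.0],
            [0.5, 0.5, 0.0],
            [3.0, 0.0, 4.0],
        ])
        comps = np.tile([46.0, 12, 18, 14, 10], (5, 1))
        cands = select_top_candidates(obs, obs + errs, comps, k=5, standardize=False)
        expected = np.sqrt((errs**2).sum(axis=1) / 2)
        got = {c.index: c.pooled_distance for c in cands}
        for i in range(5):
            assert got[i] == pytest.approx(expected[i])
        assert [c.index for c in cands] == [3, 0, 2, 1, 4]

    def test_k_larger_than_n_errors(self):
        obs, pred, comps = _blind_fixture(5)
        with pytest.raises(FormulationError):
            select_top_candidates(obs, pred, comps, k=6)

    def test_stable_under_duplicating_nonselected(self):
        obs, pred, comps = _blind_fixture(15, seed=3)
        cands = select_top_candidates(obs, pred, comps, k=5)
        worst = max(c.index for c in select_top_candidates(obs, pred, comps, k=15))
        obs2 = np.vstack([obs, obs[worst]])
        pred2 = np.vstack([pred, pred[worst]])
        comps2 = np.vstack([comps, comps[worst]])
        cands2 = select_top_candidates(obs2, pred2, comps2, k=5)
        assert [c.index for c in cands] == [c.index for c in cands2]


class TestRerank:
    def test_equal_reliability_preserves_distance_order(self):
        class FlatModel:
            def stage_prediction_spread(self, comps):
                return np.ones((len(comps), 3))

        obs, pred, comps = _blind_fixture()
        cands = select_top_candidates(obs, pred, comps, k=8)
        rer = rerank_by_loss_weights(cands, FlatModel())
        assert [c.index for c in rer] == [c.index for c in cands]

    def test_lower_spread_wins_ties(self):
        class SpreadModel:
            def stage_prediction_spread(self, comps):
                # second candidate has lower spread
                return np.array([[2.0, 2, 2], [0.5, 0.5, 0.5]])

        obs = np.zeros((2, 3))
        errs = np.array([[1.0, 1, 1], [1.0, 1, 1]])  # equidistant
        comps = np.tile([46.0, 12, 18, 14, 10], (2, 1))
        cands = select_top_candidates(obs, obs + errs, comps, k=2, standardize=False)
        rer = rerank_by_loss_weights(cands, SpreadModel())
        assert rer[0].index == 1

    def test_membership_never_changes(self, desk_predictions, desk_model):
        obs, pred, blind = desk_predictions
        cands = select_top_candidates(obs, pred, blind.compositions(), k=10)
        rer = rerank_by_loss_weights(cands, desk_model)
        assert {c.index for c in rer} == {c.index for c in cands}
        assert sorted(c.rank for c in rer) == list(range(1, 11))


class TestCorrelationMatrix:
    def test_cqa_equal_to_lipid_gives_unit_entry(self):
        rng = np.random.default_rng(1)
        comps = rng.dirichlet(np.ones(5) * 10, size=50) * 100
        cqas = np.column_stack([comps[:, 0], rng.normal(0.15, 0.01, 50), rng.normal(-35, 2, 50)])
        m = cma_cqa_correlation(comps, cqas)
        assert m.values.loc["chol", "size_nm"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        comps = rng.dirichlet(np.ones(5) * 10, size=10000) * 100
        cqas = rng.normal(0, 1, size=(10000, 3)) + [[120, 0.15, -35]]
        m = cma_cqa_correlation(comps, cqas)
        assert np.abs(m.values.to_numpy()).max() < 0.05

    def test_matches_reference_pearson(self):
        rng = np.random.default_rng(3)
        comps = rng.dirichlet(np.ones(5) * 10, size=20) * 100
        cqas = rng.normal([120, 0.15, -35], [5, 0.02, 2], size=(20, 3))
        m = cma_cqa_correlation(comps, cqas).values.to_numpy()
        ref = np.corrcoef(comps.T, cqas.T)[:5, 5:]
        assert np.allclose(m, ref, atol=1e-12)

    def test_rmse_normalized_scales_but_keeps_signs(self):
        rng = np.random.default_rng(4)
        comps = rng.dirichlet(np.ones(5) * 10, size=100) * 100
        cqas = np.column_stack([
            120 - comps[:, 2], 0.15 + 0.001 * comps[:, 1], -35 - 0.3 * comps[:, 4]
        ])
        raw = cma_cqa_correlation(comps, cqas, mode="raw")
        norm = cma_cqa_correlation(
            comps, cqas, mode="rmse_normalized", blind_rmse=np.array([2.0, 0.01, 1.0])
        )
        assert np.all(np.sign(norm.values.to_numpy()) == np.sign(raw.values.to_numpy()))
        assert np.all(np.abs(norm.values.to_numpy()) <= np.abs(raw.values.to_numpy()) + 1e-12)
        assert "rmse_factor" in norm.metadata

    def test_zero_variance_flagged(self):
        comps = np.tile([46.0, 12, 18, 14, 10], (20, 1))
        cqas = np.random.default_rng(5).normal([120, 0.15, -35], 1, size=(20, 3))
        m = cma_cqa_correlation(comps, cqas)
        assert np.isnan(m.values.to_numpy()).all()
        assert len(m.metadata["undefined"]) == 15

    def test_pc_row_negative_on_default_pipeline(self, desk_predictions):
        obs, _, blind = desk_predictions
        m = cma_cqa_correlation(blind.compositions(), obs)
        assert (m.values.loc["pc"] < 0).all()


class TestProfiles:
    def test_each_profile_returns_exactly_k(self, desk_predictions):
        obs, pred, blind = desk_predictions
        for profile in DEFAULT_PROFILES.values():
            cands = rank_for_profile(obs, pred, blind.compositions(), profile, k=10)
            assert len(cands) == 10
            assert [c.rank for c in cands] == list(range(1, 11))

    def test_composition_affinity_steers_selection(self):
        obs = np.zeros((3, 3))
        pred = obs.copy()  # all equally (perfectly) predicted
        comps = np.array([
            [46.0, 12, 19, 13, 10],  # matches the HeLa profile targets
            [60.0, 10, 10, 10, 10],
            [30.0, 20, 30, 10, 10],
        ])
        cands = rank_for_profile(obs, pred, comps, DEFAULT_PROFILES["HeLa"], k=3)
        assert cands[0].index == 0
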