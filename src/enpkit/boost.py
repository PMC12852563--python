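"""Hybrid least-squares boosting ensemble with normalized-RMSE stage weighting.

The regressor maps a five-lipid composition to one quality attribute by
stage-wise boosting of regression trees:

    F_n(x) = F_{n-1}(x) + y_n * W_n(x, E_n)

where W_n is a tree fit to the current residuals under per-sample weights,
and y_n is derived from a min–max normalization of the stage RMSEs within an
epoch:

    y_n = (RMSE_n - RMSE_min) / (RMSE_max - RMSE_min)

Training runs in epochs of ``iterations_per_epoch`` stages. Within an epoch,
stages are applied with the provisional multiplier ``learning_rate``; at the
epoch boundary the normalized stage weights are recomputed over the epoch's
stages and the applied multipliers become ``learning_rate * w(y_n)``, where

    w(y) = 1 - y   ("inverted", default: down-weights the worst-fitting stage)
    w(y) = y       ("as_printed": the raw normalized ranking itself)
    w(y) = 1       ("uniform": plain least-squares gradient boosting)

The epoch boundary also re-weights samples proportionally to
``1 + |residual| / max|residual|``, so hard-to-predict samples get up to twice
the weight in the next epoch's tree fits. Each stage records a feature
equation E_n: per-feature split-gain importances plus signed partial effects
(mean stage prediction over the feature's top quartile minus its bottom
quartile).

Three such ensembles — one per quality attribute — sit behind one facade.
Internally features are compositions divided by 100 (0–1 fractions); the
public interface takes mol% on the 0–100 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .data import CQAS, LIPIDS, CQAVector, FormulationDataset, FormulationError

WEIGHT_MODES = ("inverted", "as_printed", "uniform")


@dataclass(frozen=True)
class BoostConfig:
    leaf_size: int = 8
    learning_rate: float = 0.02
    epochs: int = 10
    iterations_per_epoch: int = 50
    weight_mode: str = "inverted"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise FormulationError("learning_rate must be in (0, 1]")
        if self.leaf_size < 1:
            raise FormulationError("leaf_size must be >= 1")
        if self.epochs * self.iterations_per_epoch < 1:
            raise FormulationError("need at least one boosting stage")
        if self.weight_mode not in WEIGHT_MODES:
            raise FormulationError(f"weight_mode must be one of {WEIGHT_MODES}")


def allocate_stage_weights(stage_rmses: Sequence[float]) -> np.ndarray:
    """Min–max normalized RMSE ranking over one epoch's stages.

    All-equal RMSEs (including a single stage) give all zeros by convention.
    """
    r = np.asarray(stage_rmses, dtype=float)
    if r.size < 1:
        raise FormulationError("need at least one stage")
    span = r.max() - r.min()
    if span == 0:
        return np.zeros_like(r)
    return (r - r.min()) / span


@dataclass(frozen=True)
class FeatureEquation:
    """Split-gain importances and signed high-vs-low-quartile partial effects."""

    importances: np.ndarray  # (5,) >= 0, sum to 1 when any split exists
    partial_effects: np.ndarray  # (5,) signed
    degenerate: bool = False  # no splits


class _ArrayTree:
    """Prediction-only regression tree reconstructed from serialized arrays."""

    def __init__(self, children_left, children_right, feature, threshold, value):
        self.children_left = np.asarray(children_left)
        self.children_right = np.asarray(children_right)
        self.feature = np.asarray(feature)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        active = self.children_left[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] >= 0
        return self.value[node]


def _tree_to_dict(tree: DecisionTreeRegressor) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.ravel().tolist(),
    }


@dataclass
class BoostStage:
    tree: object  # DecisionTreeRegressor or _ArrayTree
    raw_weight: float  # y_n straight from the normalized-RMSE ranking
    applied_multiplier: float  # learning_rate * w(y_n)
    stage_rmse: float
    feature_equation: FeatureEquation


@dataclass
class SingleEnsemble:
    """Boosted ensemble for one quality attribute."""

    target: str
    f0: float
    stages: list[BoostStage]
    rmse_trace: list[float]  # training RMSE at each epoch boundary
    constant: bool = False  # degenerate zero-variance target

    def predict(self, X01: np.ndarray) -> np.ndarray:
        pred = np.full(len(X01), self.f0)
        for st in self.stages:
            if st.applied_multiplier != 0.0:
                pred = pred + st.applied_multiplier * st.tree.predict(X01)
        return pred

    def stage_contributions(self, X01: np.ndarray) -> np.ndarray:
        """(n_samples, n_stages) matrix of applied stage contributions."""
        out = np.empty((len(X01), len(self.stages)))
        for j, st in enumerate(self.stages):
            out[:, j] = st.applied_multiplier * st.tree.predict(X01)
        return out


def _feature_equation(
    tree: DecisionTreeRegressor, pred: np.ndarray, hi_masks: list, lo_masks: list
) -> FeatureEquation:
    if tree.tree_.node_count <= 1:
        return FeatureEquation(np.zeros(5), np.zeros(5), degenerate=True)
    imp = tree.feature_importances_.copy()
    effects = np.array(
        [pred[hi_masks[j]].mean() - pred[lo_masks[j]].mean() for j in range(5)]
    )
    return FeatureEquation(imp, effects)


def _fit_single(
    X01: np.ndarray, y: np.ndarray, target: str, cfg: BoostConfig, rng: np.random.Generator
) -> SingleEnsemble:
    n = len(y)
    f0 = float(y.mean())
    if np.ptp(y) == 0.0:
        return SingleEnsemble(target, float(y[0]), [], [0.0], constant=True)
    if n < 2 * cfg.leaf_size:
        raise FormulationError(f"need >= {2 * cfg.leaf_size} records, got {n}")

    q25 = np.quantile(X01, 0.25, axis=0)
    q75 = np.quantile(X01, 0.75, axis=0)
    hi_masks = [X01[:, j] >= q75[j] for j in range(5)]
    lo_masks = [X01[:, j] <= q25[j] for j in range(5)]

    F = np.full(n, f0)
    sample_w = np.ones(n)
    stages: list[BoostStage] = []
    rmse_trace: list[float] = []
    lr = cfg.learning_rate

    for _epoch in range(cfg.epochs):
        F_start = F.copy()
        epoch_trees: list[DecisionTreeRegressor] = []
        epoch_preds: list[np.ndarray] = []
        epoch_rmses: list[float] = []
        epoch_eqs: list[FeatureEquation] = []
        for _it in range(cfg.iterations_per_epoch):
            resid = y - F
            tree = DecisionTreeRegressor(
                criterion="squared_error",
                min_samples_leaf=cfg.leaf_size,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X01, resid, sample_weight=sample_w)
            pred = tree.predict(X01)
            F = F + lr * pred  # provisional within-epoch multiplier
            epoch_trees.append(tree)
            epoch_preds.append(pred)
            epoch_rmses.append(float(np.sqrt(np.mean((y - F) ** 2))))
            epoch_eqs.append(_feature_equation(tree, pred, hi_masks, lo_masks))

        # epoch boundary: Eq.-6 weights over this epoch's stages
        y_n = allocate_stage_weights(epoch_rmses)
        if cfg.weight_mode == "inverted":
            w = 1.0 - y_n
        elif cfg.weight_mode == "as_printed":
            w = y_n.copy()
        else:  # uniform
            w = np.ones_like(y_n)
        multipliers = lr * w
        F = F_start + sum(m * p for m, p in zip(multipliers, epoch_preds))
        resid = y - F
        max_abs = np.max(np.abs(resid))
        sample_w = 1.0 + (np.abs(resid) / max_abs) if max_abs > 0 else np.ones(n)
        sample_w = sample_w * (n / sample_w.sum())
        rmse_trace.append(float(np.sqrt(np.mean(resid**2))))

        for tree, yn, mult, srmse, eq in zip(
            epoch_trees, y_n, multipliers, epoch_rmses, epoch_eqs
        ):
            stages.append(BoostStage(tree, float(yn), float(mult), srmse, eq))

        if cfg.weight_mode == "inverted" and len(rmse_trace) > 1:
            prev, cur = rmse_trace[-2], rmse_trace[-1]
            if cur > prev * (1 + 1e-8):
                raise FormulationError(
                    f"training RMSE increased ({prev:.6g} -> {cur:.6g}) in inverted mode"
                )

    return SingleEnsemble(target, f0, stages, rmse_trace)


class EnsembleModel:
    """Per-CQA boosted ensembles behind one multi-output facade."""

    def __init__(self, cfg: Optional[BoostConfig] = None):
        self.cfg = cfg or BoostConfig()
        self.ensembles: dict[str, SingleEnsemble] = {}

    @property
    def is_fitted(self) -> bool:
        return bool(self.ensembles)

    def fit(self, train: FormulationDataset) -> "EnsembleModel":
        if not train.has_cqas:
            raise FormulationError("all training records need CQA labels")
        X01 = train.compositions() / 100.0
        Y = train.cqas()
        rng = np.random.default_rng(self.cfg.seed)
        # the three per-CQA ensembles are independent; sequential order is a
        # deterministic schedule, not a data dependency
        for j, target in enumerate(CQAS):
            sub_rng = np.random.default_rng(rng.integers(2**31 - 1))
            self.ensembles[target] = _fit_single(X01, Y[:, j], target, self.cfg, sub_rng)
        return self

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise FormulationError("model is not trained")

    def predict(self, compositions: np.ndarray) -> np.ndarray:
        """(n, 5) mol% compositions → (n, 3) predicted CQAs."""
        self._check_fitted()
        X01 = np.atleast_2d(np.asarray(compositions, dtype=float)) / 100.0
        return np.column_stack([self.ensembles[t].predict(X01) for t in CQAS])

    def predict_one(self, composition) -> CQAVector:
        row = self.predict(composition.as_array()[None, :])[0]
        return CQAVector(*row)

    def stage_prediction_spread(self, compositions: np.ndarray) -> np.ndarray:
        """Per-record, per-CQA std of applied stage contributions (n, 3).

        A small spread means the stages agree on how to move the prediction —
        the model's per-record confidence proxy.
        """
        self._check_fitted()
        X01 = np.atleast_2d(np.asarray(compositions, dtype=float)) / 100.0
        cols = []
        for t in CQAS:
            ens = self.ensembles[t]
            if not ens.stages:
                cols.append(np.zeros(len(X01)))
            else:
                cols.append(ens.stage_contributions(X01).std(axis=1))
        return np.column_stack(cols)

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        out = {"config": asdict(self.cfg), "ensembles": {}}
        for t, ens in self.ensembles.items():
            out["ensembles"][t] = {
                "f0": ens.f0,
                "constant": ens.constant,
                "rmse_trace": ens.rmse_trace,
                "stages": [
                    {
                        "tree": _tree_to_dict(st.tree)
                        if isinstance(st.tree, DecisionTreeRegressor)
                        else {
                            "children_left": st.tree.children_left.tolist(),
                            "children_right": st.tree.children_right.tolist(),
                            "feature": st.tree.feature.tolist(),
                            "threshold": st.tree.threshold.tolist(),
                            "value": st.tree.value.tolist(),
                        },
                        "raw_weight": st.raw_weight,
                        "applied_multiplier": st.applied_multiplier,
                        "stage_rmse": st.stage_rmse,
                        "importances": st.feature_equation.importances.tolist(),
                        "partial_effects": st.feature_equation.partial_effects.tolist(),
                        "degenerate": st.feature_equation.degenerate,
                    }
                    for st in ens.stages
                ],
            }
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "EnsembleModel":
        model = cls(BoostConfig(**payload["config"]))
        for t, ed in payload["ensembles"].items():
            stages = [
                BoostStage(
                    tree=_ArrayTree(**sd["tree"]),
                    raw_weight=sd["raw_weight"],
                    applied_multiplier=sd["applied_multiplier"],
                    stage_rmse=sd["stage_rmse"],
                    feature_equation=FeatureEquation(
                        np.asarray(sd["importances"]),
                        np.asarray(sd["partial_effects"]),
                        sd["degenerate"],
                    ),
                )
                for sd in ed["stages"]
            ]
            model.ensembles[t] = SingleEnsemble(
                t, ed["f0"], stages, ed["rmse_trace"], ed["constant"]
            )
        return model

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def extract_feature_equations(model: EnsembleModel) -> dict[str, FeatureEquation]:
    """Aggregate per-stage feature equations into one summary per CQA.

    Importances are averaged weighted by |applied multiplier| (renormalized to
    sum to 1 when any split exists); partial effects are the multiplier-
    weighted sum, i.e. the ensemble-scale high-vs-low-quartile effect.
    """
    model._check_fitted()
    out: dict[str, FeatureEquation] = {}
    for t, ens in model.ensembles.items():
        live = [s for s in ens.stages if not s.feature_equation.degenerate]
        if not live:
            out[t] = FeatureEquation(np.zeros(5), np.zeros(5), degenerate=True)
            continue
        weights = np.array([abs(s.applied_multiplier) for s in live])
        imps = np.array([s.feature_equation.importances for s in live])
        effects = np.array([s.feature_equation.partial_effects for s in live])
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        agg_imp = (weights[:, None] * imps).sum(axis=0)
        if agg_imp.sum() > 0:
            agg_imp = agg_imp / agg_imp.sum()
        agg_eff = np.array(
            [s.applied_multiplier for s in live]
        )[:, None] * effects
        out[t] = FeatureEquation(agg_imp, agg_eff.sum(axis=0))
    return out
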