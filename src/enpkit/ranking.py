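"""Blind-test candidate selection and ranking.

In a prediction-vs-observation scatter, a perfectly predicted formulation sits
on the identity (1:1) line; the perpendicular distance of (observed,
predicted) to that line, |pred − obs|/√2, measures per-record prediction
error. Candidates are ranked by a pooled distance over the three quality
attributes (each distance standardized by that attribute's blind RMSE so the
units nm / — / mV are comparable), then optionally re-ranked by a reliability
factor derived from the ensemble's stage-prediction spread: among equally
close candidates, those the ensemble is most internally consistent about rank
first.

The module also computes the CMA–CQA association matrix (Pearson, optionally
with columns scaled by 1 − normalized blind RMSE so better-predicted
attributes keep more weight) and supports per-cell-line target profiles that
bias the ranking toward compositional regions favoured by each cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import CQAS, LIPIDS, FormulationDataset, FormulationError

_SQRT2 = np.sqrt(2.0)


def identity_line_distance(pred, actual) -> np.ndarray | float:
    """Perpendicular distance of (actual, pred) to the line pred = actual."""
    return np.abs(np.asarray(pred, dtype=float) - np.asarray(actual, dtype=float)) / _SQRT2


@dataclass
class RankedCandidate:
    index: int  # position in the blind set
    composition: np.ndarray  # (5,) mol%
    per_cqa_distance: np.ndarray  # (3,) identity-line distances
    pooled_distance: float
    reliability: float = 1.0
    score: float = 0.0
    rank: int = 0


def select_top_candidates(
    observed: np.ndarray,
    predicted: np.ndarray,
    compositions: np.ndarray,
    k: int = 10,
    standardize: bool = True,
) -> list[RankedCandidate]:
    """Pick the k blind-set records closest to the 1:1 line, pooled over CQAs.

    Pooled distance is sqrt(sum_c (d_c / s_c)^2) with s_c the per-CQA blind
    RMSE when ``standardize`` is on (1 otherwise). Ascending sort, ties broken
    by record order.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    compositions = np.asarray(compositions, dtype=float)
    n = len(observed)
    if k > n:
        raise FormulationError(f"k={k} exceeds blind-set size {n}")
    d = identity_line_distance(predicted, observed)  # (n, 3)
    if standardize:
        s = np.sqrt(np.mean((predicted - observed) ** 2, axis=0))
        s = np.where(s == 0, 1.0, s)
    else:
        s = np.ones(observed.shape[1])
    pooled = np.sqrt(np.sum((d / s) ** 2, axis=1))
    order = np.argsort(pooled, kind="stable")[:k]
    out = []
    for rank, i in enumerate(order, start=1):
        out.append(
            RankedCandidate(
                index=int(i),
                composition=compositions[i].copy(),
                per_cqa_distance=d[i].copy(),
                pooled_distance=float(pooled[i]),
                score=float(pooled[i]),
                rank=rank,
            )
        )
    return out


def rerank_by_loss_weights(
    candidates: Sequence[RankedCandidate], model
) -> list[RankedCandidate]:
    """Re-rank candidates by distance scaled with a model-reliability factor.

    The reliability factor comes from the ensemble's stage-prediction spread
    at the candidate's composition: spreads are normalized by each CQA's blind
    RMSE proxy (the mean spread over candidates), and
    reliability = 1 / (1 + mean normalized spread). The final score is
    pooled_distance / reliability, so low-spread (high-confidence) candidates
    win ties. Membership of the set never changes, only order.
    """
    if not candidates:
        return []
    comps = np.array([c.composition for c in candidates])
    spread = model.stage_prediction_spread(comps)  # (k, 3)
    denom = spread.mean(axis=0)
    denom = np.where(denom == 0, 1.0, denom)
    norm_spread = (spread / denom).mean(axis=1)
    out = []
    for cand, ns in zip(candidates, norm_spread):
        rel = 1.0 / (1.0 + float(ns))
        out.append(
            RankedCandidate(
                index=cand.index,
                composition=cand.composition,
                per_cqa_distance=cand.per_cqa_distance,
                pooled_distance=cand.pooled_distance,
                reliability=rel,
                score=cand.pooled_distance / rel,
            )
        )
    out.sort(key=lambda c: (c.score, c.index))
    for rank, cand in enumerate(out, start=1):
        cand.rank = rank
    return out


def candidates_frame(candidates: Sequence[RankedCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {"rank": c.rank, "blind_index": c.index}
        row.update(zip(LIPIDS, c.composition))
        row.update({f"d_{name}": v for name, v in zip(CQAS, c.per_cqa_distance)})
        row.update(
            {"pooled_distance": c.pooled_distance, "reliability": c.reliability, "score": c.score}
        )
        rows.append(row)
    return pd.DataFrame(rows)


# -- CMA–CQA association matrix ----------------------------------------------


@dataclass(frozen=True)
class CorrelationMatrix:
    values: pd.DataFrame  # 5 lipids × 3 CQAs
    mode: str  # "raw" | "rmse_normalized"
    metadata: dict = field(default_factory=dict)


def cma_cqa_correlation(
    compositions: np.ndarray,
    cqas: np.ndarray,
    mode: str = "raw",
    blind_rmse: Optional[np.ndarray] = None,
    cqa_ranges: Optional[np.ndarray] = None,
) -> CorrelationMatrix:
    """Signed association of each lipid fraction with each quality attribute.

    Raw mode is the plain Pearson matrix. In "rmse_normalized" mode each CQA
    column is scaled by (1 − blind_rmse / range), so attributes the model
    predicts poorly contribute less; signs are never changed. Zero-variance
    columns yield NaN entries (flagged in metadata).
    """
    compositions = np.asarray(compositions, dtype=float)
    cqas = np.asarray(cqas, dtype=float)
    n = len(compositions)
    if n < 10:
        raise FormulationError("association matrix needs n >= 10")
    mat = np.full((5, 3), np.nan)
    undefined = []
    for i in range(5):
        for j in range(3):
            x, y = compositions[:, i], cqas[:, j]
            if np.std(x) == 0 or np.std(y) == 0:
                undefined.append((LIPIDS[i], CQAS[j]))
                continue
            mat[i, j] = np.corrcoef(x, y)[0, 1]
    meta: dict = {"undefined": undefined}
    if mode == "rmse_normalized":
        if blind_rmse is None:
            raise FormulationError("rmse_normalized mode needs per-CQA blind RMSEs")
        rng = np.asarray(
            cqa_ranges if cqa_ranges is not None else np.ptp(cqas, axis=0), dtype=float
        )
        rng = np.where(rng == 0, 1.0, rng)
        factor = np.clip(1.0 - np.asarray(blind_rmse, dtype=float) / rng, 0.0, 1.0)
        mat = mat * factor[None, :]
        meta["rmse_factor"] = factor.tolist()
        meta["blind_rmse"] = np.asarray(blind_rmse, dtype=float).tolist()
    elif mode != "raw":
        raise FormulationError(f"unknown mode {mode!r}")
    mat = np.clip(mat, -1.0, 1.0)
    frame = pd.DataFrame(mat, index=list(LIPIDS), columns=list(CQAS))
    return CorrelationMatrix(frame, mode, meta)


# -- per-cell-line target profiles ---------------------------------------------


@dataclass(frozen=True)
class CellLineProfile:
    """Compositional preferences of one target cell line.

    ``composition_targets`` maps lipid → (target mol%, weight); the affinity
    penalty w·|fraction − target|/100 is added to the prediction-quality score,
    steering the top-k toward compositions that cell line favours.
    ``cqa_weights`` rescale the per-CQA identity-line distances.
    """

    name: str
    cqa_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    composition_targets: dict = field(default_factory=dict)


#: Illustrative profiles for the three carcinoma lines commonly screened with
#: ENPs: cholesterol-rich, PC >= ~19% for HeLa and MCF-7; H1975 tolerates lower
#: cholesterol and is steered by PS/PE content.
DEFAULT_PROFILES: dict[str, CellLineProfile] = {
    "HeLa": CellLineProfile(
        "HeLa", composition_targets={"chol": (46.0, 1.0), "pc": (19.0, 1.0)}
    ),
    "MCF7": CellLineProfile(
        "MCF7", composition_targets={"chol": (46.0, 1.0), "pc": (19.0, 1.5)}
    ),
    "H1975": CellLineProfile(
        "H1975",
        composition_targets={"chol": (40.5, 0.5), "ps": (12.0, 1.5), "pe": (14.0, 1.0)},
    ),
}


def rank_for_profile(
    observed: np.ndarray,
    predicted: np.ndarray,
    compositions: np.ndarray,
    profile: CellLineProfile,
    k: int = 10,
) -> list[RankedCandidate]:
    """Top-k candidates for one cell-line profile.

    The pooled distance uses the profile's CQA weights; the profile's
    composition affinity is added to the score before the final sort.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    compositions = np.asarray(compositions, dtype=float)
    n = len(observed)
    if k > n:
        raise FormulationError(f"k={k} exceeds blind-set size {n}")
    d = identity_line_distance(predicted, observed)
    s = np.sqrt(np.mean((predicted - observed) ** 2, axis=0))
    s = np.where(s == 0, 1.0, s)
    w = np.asarray(profile.cqa_weights, dtype=float)
    pooled = np.sqrt(np.sum((w * d / s) ** 2, axis=1))
    affinity = np.zeros(n)
    for lipid, (target, weight) in profile.composition_targets.items():
        j = LIPIDS.index(lipid)
        affinity += weight * np.abs(compositions[:, j] - target) / 100.0
    score = pooled + affinity
    order = np.argsort(score, kind="stable")[:k]
    out = []
    for rank, i in enumerate(order, start=1):
        out.append(
            RankedCandidate(
                index=int(i),
                composition=compositions[i].copy(),
                per_cqa_distance=d[i].copy(),
                pooled_distance=float(pooled[i]),
                score=float(score[i]),
                rank=rank,
            )
        )
    return out
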