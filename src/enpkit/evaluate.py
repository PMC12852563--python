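"""Model evaluation: error metrics, residual analysis, ROC over accuracy
classes, Monte Carlo cross-validation, and the ablation harness.

Metric conventions
------------------
MAE, MSE and RMSE are the usual sample means of |e|, e² and √MSE. The
correlation statistic ``eq10`` is the Pearson correlation between predicted
and observed values; its square (``eq10_sq``) is the conventional coefficient
of determination for a linear fit. Both are reported: model-performance
claims in this package quote ``eq10``.

MCCV repeats a stratified 70/30 split, retrains from scratch each iteration,
and averages a per-iteration error ε_i. Since the three quality attributes
live on different scales (nm / dimensionless / mV), ε_i is defined as the
mean over CQAs of the blind RMSE after min–max scaling each CQA by its
training-set range, giving a unit-free number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .data import CQAS, FormulationDataset, FormulationError, split_dataset


@dataclass(frozen=True)
class Metrics:
    mae: float
    mse: float
    rmse: float
    eq10: float  # Pearson correlation between prediction and observation
    eq10_sq: float
    degenerate: bool = False  # zero variance: correlation undefined


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise FormulationError("predicted and observed vectors must match in length")
    if len(y_true) < 2:
        raise FormulationError("metrics need n >= 2")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return Metrics(mae, mse, rmse, float("nan"), float("nan"), degenerate=True)
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Metrics(mae, mse, rmse, r, r * r)


def metrics_report(
    observed: np.ndarray, predicted: np.ndarray
) -> dict[str, Metrics]:
    """Per-CQA metrics plus a pooled row over all three attributes z-scored."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    report = {name: compute_metrics(observed[:, j], predicted[:, j]) for j, name in enumerate(CQAS)}
    mu = observed.mean(axis=0)
    sd = observed.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    report["pooled"] = compute_metrics(
        ((observed - mu) / sd).ravel(), ((predicted - mu) / sd).ravel()
    )
    return report


@dataclass(frozen=True)
class ResidualReport:
    residuals: np.ndarray
    mean: float
    skewness: float
    sign_test_p: float  # binomial test of positive vs negative residuals
    unbiased: bool  # |mean| within 2 standard errors of zero


def residual_analysis(y_true: np.ndarray, y_pred: np.ndarray) -> ResidualReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 3:
        raise FormulationError("residual analysis needs n >= 3")
    e = y_true - y_pred
    mean = float(e.mean())
    skew = float(stats.skew(e)) if np.std(e) > 0 else 0.0
    n_pos = int(np.sum(e > 0))
    n_neg = int(np.sum(e < 0))
    if n_pos + n_neg == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue)
    se = float(e.std(ddof=1) / np.sqrt(len(e))) if np.std(e) > 0 else 0.0
    unbiased = abs(mean) <= 2 * se if se > 0 else mean == 0
    return ResidualReport(e, mean, skew, p, unbiased)


def roc_accuracy(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    score: np.ndarray,
    tau: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of a confidence score against high/low prediction-accuracy classes.

    A record is "high accuracy" when its absolute residual is at most ``tau``
    (default: the median absolute residual, which guarantees two non-empty
    classes for continuous residuals). Returns (fpr, tpr, auc); the AUC is the
    trapezoidal area.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    score = np.asarray(score, dtype=float)
    abs_err = np.abs(y_true - y_pred)
    if tau is None:
        tau = float(np.median(abs_err))
    labels = (abs_err <= tau).astype(int)
    if labels.min() == labels.max():
        raise FormulationError(
            f"accuracy threshold tau={tau!r} produces a single class; choose another tau"
        )
    fpr, tpr, _ = _roc_curve(labels, score)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


@dataclass
class MCCVReport:
    epsilons: np.ndarray  # ε_i, one per iteration
    epsilon_mean: float  # ε_MCCV
    rmse: pd.DataFrame  # iterations × CQAs
    eq10: pd.DataFrame  # iterations × CQAs

    @property
    def iterations(self) -> int:
        return len(self.epsilons)


def mccv(
    ds: FormulationDataset,
    model_factory: Callable[[], object],
    iterations: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    stratify_on: Optional[str] = "size_nm",
) -> MCCVReport:
    """Monte Carlo cross-validation: repeated stratified splits, full retrains.

    ``model_factory()`` must return a fresh object with
    ``fit(FormulationDataset)`` and ``predict((n, 5) mol%) -> (n, 3)``.
    """
    if iterations < 1:
        raise FormulationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(2**31 - 1, size=iterations)
    eps, rmse_rows, r_rows = [], [], []
    for i in range(iterations):
        try:
            train, blind = split_dataset(
                ds, train_frac, seed=int(split_seeds[i]), stratify_on=stratify_on
            )
            model = model_factory()
            model.fit(train)
            pred = model.predict(blind.compositions())
        except Exception as exc:  # abort with the failing iteration index
            raise FormulationError(f"MCCV iteration {i} failed: {exc}") from exc
        obs = blind.cqas()
        train_rng = np.ptp(train.cqas(), axis=0)
        train_rng = np.where(train_rng == 0, 1.0, train_rng)
        per_cqa_rmse = np.sqrt(np.mean((pred - obs) ** 2, axis=0))
        eps.append(float(np.mean(per_cqa_rmse / train_rng)))
        rmse_rows.append(per_cqa_rmse)
        r_rows.append(
            [compute_metrics(obs[:, j], pred[:, j]).eq10 for j in range(3)]
        )
    return MCCVReport(
        epsilons=np.asarray(eps),
        epsilon_mean=float(np.mean(eps)),
        rmse=pd.DataFrame(rmse_rows, columns=list(CQAS)),
        eq10=pd.DataFrame(r_rows, columns=list(CQAS)),
    )


# -- ablation ----------------------------------------------------------------


class SklearnCQAAdapter:
    """Wraps a per-target sklearn-style regressor behind the dataset interface."""

    def __init__(self, estimator_factory: Callable[[], object]):
        self._factory = estimator_factory
        self._models: list[object] = []

    def fit(self, train: FormulationDataset) -> "SklearnCQAAdapter":
        X = train.compositions() / 100.0
        Y = train.cqas()
        self._models = []
        for j in range(Y.shape[1]):
            est = self._factory()
            est.fit(X, Y[:, j])
            self._models.append(est)
        return self

    def predict(self, compositions: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(compositions, dtype=float)) / 100.0
        return np.column_stack([m.predict(X) for m in self._models])


def default_baselines(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Factories for the conventional regressors the hybrid is benchmarked against."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import LinearRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    baselines: dict[str, Callable[[], object]] = {
        "MLR": lambda: SklearnCQAAdapter(LinearRegression),
        "SVM": lambda: SklearnCQAAdapter(
            lambda: make_pipeline(StandardScaler(), SVR())
        ),
        "RF": lambda: SklearnCQAAdapter(
            lambda: RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
        ),
    }
    try:
        from xgboost import XGBRegressor

        baselines["XGBoost"] = lambda: SklearnCQAAdapter(
            lambda: XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
        )
    except ImportError:  # pragma: no cover - xgboost optional at runtime
        pass
    return baselines


def ablation(
    ds: FormulationDataset,
    hybrid_factory: Callable[[], object],
    baselines: Optional[dict[str, Callable[[], object]]] = None,
    train_frac: float = 0.7,
    seed: int = 0,
    stratify_on: Optional[str] = "size_nm",
) -> pd.DataFrame:
    """Benchmark the hybrid against conventional regressors on one shared split.

    Returns a tidy table with one row per (method, CQA) carrying RMSE, MAE and
    the correlation statistic. A baseline whose fit fails is marked skipped and
    the run continues.
    """
    if baselines is None:
        baselines = default_baselines(seed)
    train, blind = split_dataset(ds, train_frac, seed=seed, stratify_on=stratify_on)
    obs = blind.cqas()
    rows = []
    methods = {"hybrid": hybrid_factory, **baselines}
    for name, factory in methods.items():
        try:
            model = factory()
            model.fit(train)
            pred = model.predict(blind.compositions())
        except Exception as exc:
            for cqa in CQAS:
                rows.append(
                    {"method": name, "cqa": cqa, "rmse": np.nan, "mae": np.nan,
                     "eq10": np.nan, "skipped": True, "error": str(exc)}
                )
            continue
        for j, cqa in enumerate(CQAS):
            m = compute_metrics(obs[:, j], pred[:, j])
            rows.append(
                {"method": name, "cqa": cqa, "rmse": m.rmse, "mae": m.mae,
                 "eq10": m.eq10, "skipped": False, "error": ""}
            )
    table = pd.DataFrame(rows)
    table.attrs["seed"] = seed
    table.attrs["train_frac"] = train_frac
    table.attrs["baseline_hyperparameters"] = "library defaults with fixed seed"
    return table
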