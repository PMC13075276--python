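"""LAI regression models: grid-searched, five-fold cross-validated.

Four families are compared: ordinary least-squares Linear Regression (LR),
a single Decision Tree (DT), a bagged Random Forest (RF, prediction = mean
of its trees) and gradient-boosted trees (XGBoost, prediction = sum of
shrunken trees). Hyperparameters are selected by exhaustive grid search on
mean cross-validated RMSE, with ties broken toward the simpler model
(fewer estimators, then shallower trees). Performance is summarized by
R^2, RMSE, nRMSE (RMSE as a percent of the observed LAI range), MAE and
Bias = mean(predicted - observed), averaged over the five folds.

Estimator fitting is delegated to scikit-learn and xgboost; search, fold
handling and metrics are in-package. Feature normalization can be fit on
training folds only (leakage-safe default) or on all rows ("paper mode").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from .features import FEATURE_COLUMNS, FeatureTable, normalize_features

__all__ = [
    "ModelSpec", "CVResult", "DEFAULT_GRIDS", "make_estimator",
    "fit_predict", "evaluate_metrics", "make_folds", "cross_validate",
    "grid_search_cv",
]

FAMILIES = ("LR", "DT", "RF", "XGBoost")

#: Small grids superset-ing the reported optima for each family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {},
    "DT": {
        "max_depth": [5, 10],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 5, 10],
    },
    "RF": {
        "n_estimators": [100, 200],
        "max_features": ["sqrt", "log2"],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [5],
    },
    "XGBoost": {
        "n_estimators": [200],
        "max_depth": [5, 7],
        "learning_rate": [0.01, 0.1],
        "subsample": [0.8, 0.9],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameter grid and seed."""

    family: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"expected one of {FAMILIES}")

    def grid_points(self) -> list[dict]:
        grid = DEFAULT_GRIDS[self.family] if self.grid is None else self.grid
        if not grid:
            return [{}]
        keys = sorted(grid)
        points = [dict(zip(keys, vals))
                  for vals in itertools.product(*(grid[k] for k in keys))]
        if not points:
            raise ValueError("empty hyperparameter grid")
        return points


@dataclass
class CVResult:
    """Per-fold and mean cross-validation metrics for one model."""

    family: str
    params: dict
    fold_metrics: pd.DataFrame  # columns r2, rmse, nrmse, mae, bias
    fold_assignments: np.ndarray
    predictions: pd.Series      # pooled out-of-fold predictions

    @property
    def mean(self) -> pd.Series:
        return self.fold_metrics.mean()


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate the underlying estimator for a family + grid point."""
    if family == "LR":
        return LinearRegression()
    if family == "DT":
        return DecisionTreeRegressor(random_state=seed, **params)
    if family == "RF":
        return RandomForestRegressor(random_state=seed, **params)
    if family == "XGBoost":
        return XGBRegressor(random_state=seed, objective="reg:squarederror",
                            n_jobs=1, **params)
    raise ValueError(f"unknown family {family!r}")


def fit_predict(spec: ModelSpec, params: dict,
                x_train: np.ndarray, y_train: np.ndarray,
                x_test: np.ndarray):
    """Fit one grid point on the training rows and predict the test rows."""
    if len(x_train) == 0:
        raise ValueError("empty training set")
    est = make_estimator(spec.family, params, spec.seed)
    est.fit(x_train, y_train)
    return est.predict(x_test), est


def evaluate_metrics(observed, predicted) -> dict[str, float]:
    """R^2, RMSE, nRMSE (% of observed range), MAE and Bias.

    r2 = 1 - SSE/SST; bias = mean(predicted - observed), so negative bias
    means underestimation.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed/predicted length mismatch")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    err = pred - obs
    sse = float(np.sum(err ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rng = float(obs.max() - obs.min())
    if rng <= 0:
        raise ValueError("zero observed range: nRMSE undefined")
    rmse = float(np.sqrt(np.mean(err ** 2)))
    return {
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        "rmse": rmse,
        "nrmse": 100.0 * rmse / rng,
        "mae": float(np.mean(np.abs(err))),
        "bias": float(np.mean(err)),
    }


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded uniform shuffle into ``folds`` disjoint near-equal subsets."""
    if n < folds:
        raise ValueError(f"need >= {folds} rows, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, folds)):
        assignment[chunk] = k
    return assignment


def cross_validate(spec: ModelSpec, table: FeatureTable, params: dict,
                   folds: int = 5, seed: int | None = None,
                   normalization: str = "per-fold",
                   nrmse_range: str = "pooled") -> CVResult:
    """K-fold cross-validation of one grid point on a feature table.

    ``normalization``: "per-fold" refits the [-1, 1] scaling on each
    training split (leakage-safe); "all-rows" scales once on the full
    table. ``nrmse_range``: "pooled" divides each fold's RMSE by the range
    of all observed LAI; "per-fold" uses the fold's own test range.
    """
    if normalization not in ("per-fold", "all-rows"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    table = table.modelling_rows()
    y = table.lai.to_numpy(dtype=float)
    seed = spec.seed if seed is None else seed
    assignment = make_folds(len(y), folds, seed)
    pooled_range = float(y.max() - y.min())

    if normalization == "all-rows":
        norm_all = normalize_features(table)

    fold_rows = []
    preds = np.full(len(y), np.nan)
    for k in range(folds):
        test = assignment == k
        train = ~test
        if normalization == "per-fold":
            norm = normalize_features(table, fit_rows=table.data.index[train])
        else:
            norm = norm_all
        x = norm.features.to_numpy(dtype=float)
        pred, _ = fit_predict(spec, params, x[train], y[train], x[test])
        preds[test] = pred
        met = evaluate_metrics(y[test], pred)
        if nrmse_range == "pooled":
            met["nrmse"] = 100.0 * met["rmse"] / pooled_range
        fold_rows.append(met)
    return CVResult(
        family=spec.family, params=dict(params),
        fold_metrics=pd.DataFrame(fold_rows),
        fold_assignments=assignment,
        predictions=pd.Series(preds, index=table.data.index, name="prediction"),
    )


def _complexity_key(params: dict) -> tuple:
    """Tie-break ordering: fewer estimators, then shallower trees, then the
    lexicographic parameter tuple (fully deterministic)."""
    n_est = params.get("n_estimators", 0)
    depth = params.get("max_depth")
    depth = float("inf") if depth is None else depth
    return (n_est, depth, tuple(sorted((k, str(v)) for k, v in params.items())))


def grid_search_cv(spec: ModelSpec, table: FeatureTable, folds: int = 5,
                   seed: int | None = None, normalization: str = "per-fold",
                   ) -> tuple[dict, CVResult]:
    """Exhaustive grid search by mean CV RMSE; returns (best params, result).

    Deterministic given the seed: equal-RMSE grid points resolve toward the
    simpler model.
    """
    best = None
    for params in spec.grid_points():
        res = cross_validate(spec, table, params, folds=folds, seed=seed,
                             normalization=normalization)
        score = float(res.mean["rmse"])
        key = (score, _complexity_key(params))
        if best is None or key < best[0]:
            best = (key, params, res)
    return best[1], best[2]
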