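"""Drivers of yield gaps: regression forest, %IncMSE importance, partial dependence.

The yield gap of each field-year is regressed on seven candidate drivers:

    YG ~ DOS + Irrigation + AvgTemp + Tot_Rain + Nitrogen + Soil_Org_C + Plotarea

with a random forest (years pooled; the year-varying predictors carry the
year information). Importance is the classic permutation measure computed
on out-of-bag (OOB) predictions: %IncMSE, the percent increase in OOB MSE
when one predictor column is permuted. Partial dependence plots (PDPs)
give the marginal effect of one predictor — the model's mean prediction
over the data with that predictor pinned to each grid value — and the
grid values minimizing the DOS and irrigation PDPs define the "ideal
management" used in the counterfactual scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from sklearn.utils import check_random_state


def _bootstrap_indices(random_state, n_samples: int) -> np.ndarray:
    """Bootstrap sample indices of one tree, replicating sklearn's draw.

    For unweighted fits sklearn draws ``randint(0, n, n)`` from the tree's
    own ``random_state``; reproducing that here recovers each tree's
    out-of-bag rows, which sklearn does not expose publicly. A unit test
    pins this against ``oob_score_`` to catch any upstream change.
    """
    return check_random_state(random_state).randint(0, n_samples, n_samples)

__all__ = [
    "DRIVER_PREDICTORS",
    "PDPCurve",
    "fit_driver_rf",
    "oob_predict",
    "variable_importance",
    "partial_dependence",
    "optimal_management",
]

#: The seven candidate drivers, in the order they enter the model.
DRIVER_PREDICTORS = (
    "dos",
    "irrigations",
    "avg_temp_c",
    "total_rain_mm",
    "nitrogen_cgkg",
    "soc_dgkg",
    "plot_area_ha",
)

RESPONSE = "yg"
MIN_DRIVER_ROWS = 30


@dataclass
class PDPCurve:
    """Marginal predicted yield gap (kg/ha) along one predictor's grid."""

    predictor: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and curve lengths differ")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


def _design(table: pd.DataFrame, predictors=DRIVER_PREDICTORS) -> np.ndarray:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"driver table lacks predictors: {missing}")
    X = table[list(predictors)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("driver table has missing predictor values")
    return X


def fit_driver_rf(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    predictors=DRIVER_PREDICTORS,
    response: str = RESPONSE,
) -> RandomForestRegressor:
    """Pooled regression forest of yield gap on the driver predictors."""
    if len(table) < MIN_DRIVER_ROWS:
        raise ValueError(f"need >= {MIN_DRIVER_ROWS} rows, got {len(table)}")
    X = _design(table, predictors)
    y = table[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("driver table has missing response values")
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    )
    rf.fit(X, y)
    rf._driver_predictors = tuple(predictors)
    rf._driver_X = X
    rf._driver_y = y
    rf._driver_support = {p: (X[:, j].min(), X[:, j].max()) for j, p in enumerate(predictors)}
    return rf


def _oob_masks(forest: RandomForestRegressor, n: int) -> np.ndarray:
    """(n_trees, n) boolean matrix of which rows are out-of-bag per tree."""
    masks = np.empty((len(forest.estimators_), n), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        idx = _bootstrap_indices(tree.random_state, n)
        inbag = np.zeros(n, dtype=bool)
        inbag[idx] = True
        masks[t] = ~inbag
    return masks


def oob_predict(forest: RandomForestRegressor, X: np.ndarray, masks: np.ndarray | None = None) -> np.ndarray:
    """Out-of-bag prediction: row i averaged over trees whose bootstrap missed i.

    ``X`` must be row-aligned with the training matrix (the OOB pattern is
    a property of the training bootstrap, not of the feature values), which
    is exactly what permutation importance needs.
    """
    X = np.asarray(X, dtype=float)
    if masks is None:
        masks = _oob_masks(forest, len(X))
    preds = np.stack([tree.predict(X) for tree in forest.estimators_])
    counts = masks.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("some rows are never out-of-bag; grow more trees")
    return (preds * masks).sum(axis=0) / counts


def variable_importance(
    model: RandomForestRegressor,
    table: pd.DataFrame | None = None,
    n_permutations: int = 5,
    seed: int = 0,
    predictors=None,
    response: str = RESPONSE,
) -> pd.DataFrame:
    """%IncMSE permutation importance on out-of-bag predictions.

    For each predictor, its column is permuted ``n_permutations`` times;
    the reported value is the mean of
    ``100 * (OOB MSE permuted - baseline OOB MSE) / baseline OOB MSE``.
    Rows come back ranked descending (rank 1 = most important).
    """
    predictors = tuple(predictors or getattr(model, "_driver_predictors", DRIVER_PREDICTORS))
    if table is not None:
        X = _design(table, predictors)
        y = table[response].to_numpy(dtype=float)
    else:
        X, y = model._driver_X, model._driver_y
    rng = np.random.default_rng(seed)
    masks = _oob_masks(model, len(X))
    base_mse = float(np.mean((oob_predict(model, X, masks) - y) ** 2))
    rows = []
    for j, name in enumerate(predictors):
        incs = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            mse = float(np.mean((oob_predict(model, Xp, masks) - y) ** 2))
            incs.append(100.0 * (mse - base_mse) / base_mse)
        rows.append({"predictor": name, "pct_inc_mse": float(np.mean(incs))})
    out = pd.DataFrame(rows)
    out["rank"] = out["pct_inc_mse"].rank(ascending=False, method="first").astype(int)
    out.attrs["baseline_oob_mse"] = base_mse
    return out.sort_values("rank").reset_index(drop=True)


def default_grid(table: pd.DataFrame, predictor: str) -> np.ndarray:
    """Integer-day grid for DOS, observed counts for irrigation, else 50 points."""
    col = table[predictor].to_numpy(dtype=float)
    if predictor == "dos":
        return np.arange(int(np.floor(col.min())), int(np.ceil(col.max())) + 1, dtype=float)
    uniq = np.unique(col)
    if uniq.size <= 10:
        return uniq
    return np.linspace(col.min(), col.max(), 50)


def partial_dependence(
    model: RandomForestRegressor,
    table: pd.DataFrame,
    predictor: str,
    grid=None,
    predictors=None,
) -> PDPCurve:
    """Marginal-average partial dependence of predicted yield gap on one driver."""
    predictors = tuple(predictors or getattr(model, "_driver_predictors", DRIVER_PREDICTORS))
    if predictor not in predictors:
        raise ValueError(f"{predictor!r} is not a model predictor {predictors}")
    X = _design(table, predictors)
    j = predictors.index(predictor)
    if grid is None:
        grid = default_grid(table, predictor)
    grid = np.asarray(grid, dtype=float)
    lo, hi = X[:, j].min(), X[:, j].max()
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside observed {predictor} "
            f"range [{lo}, {hi}]"
        )
    values = np.empty(grid.size)
    Xg = X.copy()
    for i, v in enumerate(grid):
        Xg[:, j] = v
        values[i] = float(model.predict(Xg).mean())
    return PDPCurve(predictor=predictor, grid=grid, values=values)


def optimal_management(pdp_dos: PDPCurve, pdp_irrig: PDPCurve) -> tuple[float, float]:
    """Grid values minimizing the DOS and irrigation PDPs (smallest yield gap).

    Ties break toward earlier sowing and toward more irrigations.
    """
    if pdp_dos.grid.size == 0 or pdp_irrig.grid.size == 0:
        raise ValueError("empty partial-dependence curve")
    eps_d = 1e-12
    d_idx = int(np.argmin(pdp_dos.values))  # argmin takes the first (earliest) minimum
    best = pdp_dos.values[d_idx]
    ties = np.flatnonzero(np.isclose(pdp_dos.values, best, rtol=0, atol=eps_d))
    dos_star = float(pdp_dos.grid[ties.min()])
    best_i = pdp_irrig.values.min()
    ties_i = np.flatnonzero(np.isclose(pdp_irrig.values, best_i, rtol=0, atol=eps_d))
    irrig_star = float(pdp_irrig.grid[ties_i.max()])  # more irrigations on ties
    return dos_star, irrig_star
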