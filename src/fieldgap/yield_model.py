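"""Two-step satellite yield estimation: random forest + linear bias correction.

Step one fits, per year, a random-forest regression of crop-cut yield on
the field-mean GCVI at each scene date:

    yield ~ GCVI_1 + GCVI_2 + ... + GCVI_n.

Random-forest predictions shrink toward the training mean, so they do not
sit on the 1:1 line against observations (percent bias != 0). Step two
corrects this by ordinary least squares of observed crop-cut yield on the
forest's prediction,

    yield = beta0 + beta1 * RF_prediction + eps,

and the fitted (beta0, beta1) are applied to the forest's per-pixel
predictions to produce a bias-corrected yield raster. By the OLS normal
equations the corrected training residuals sum to zero, so the corrected
estimator has zero percent bias on its training fields by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold, ShuffleSplit

from .georef import GridGeoref
from .preprocess import GCVIStack

__all__ = [
    "YieldModel",
    "YieldRaster",
    "fit_rf_yield",
    "cross_validate",
    "pbias",
    "fit_bias_correction",
    "train_yield_model",
    "predict_pixel_yields",
    "accuracy",
]

MIN_TRAINING_FIELDS = 20
N_TREES = 500


@dataclass
class YieldModel:
    """One year's fitted two-step estimator."""

    year: int
    rf: RandomForestRegressor
    dates: list
    beta0: float
    beta1: float
    training_r2: float = np.nan
    training_rmse: float = np.nan
    pbias_raw: float = np.nan  # percent bias of the RF step before correction

    def predict_fields(self, features) -> np.ndarray:
        """Corrected predictions for a per-field GCVI feature table."""
        return self.beta0 + self.beta1 * self.rf.predict(np.asarray(features))


@dataclass
class YieldRaster:
    """Per-pixel bias-corrected yield (kg/ha) for one year."""

    year: int
    values: np.ndarray  # NaN off the cropland mask
    mask: np.ndarray  # bool, True = cropland
    georef: GridGeoref = dc_field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("yield grid and cropland mask shapes differ")

    def masked_values(self) -> np.ndarray:
        """Finite cropland pixel yields as a flat vector."""
        vals = self.values[self.mask]
        return vals[np.isfinite(vals)]


def _as_feature_matrix(features) -> np.ndarray:
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D field-by-date table")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    return X


def fit_rf_yield(
    features,
    yields,
    seed: int = 0,
    n_trees: int = N_TREES,
    min_fields: int = MIN_TRAINING_FIELDS,
) -> RandomForestRegressor:
    """Fit the step-one regression forest of crop-cut yield on per-date GCVI."""
    X = _as_feature_matrix(features)
    y = np.asarray(yields, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} feature rows vs {len(y)} yields")
    if len(X) < min_fields:
        raise ValueError(f"need >= {min_fields} training fields, got {len(X)}")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def pbias(observed, predicted) -> float:
    """Percent bias, ``100 * sum(predicted - observed) / sum(observed)``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    denom = obs.sum()
    if denom == 0:
        raise ValueError("sum of observed yields is zero; PBIAS undefined")
    return float(100.0 * (pred - obs).sum() / denom)


def fit_bias_correction(observed, rf_predicted) -> tuple[float, float]:
    """OLS of observed crop-cut yield on RF-predicted yield -> (beta0, beta1)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(rf_predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need >= 3 points for the bias-correction regression")
    if np.ptp(pred) == 0:
        raise ValueError("RF predictions are constant; bias slope undefined")
    A = np.column_stack([np.ones_like(pred), pred])
    (beta0, beta1), *_ = np.linalg.lstsq(A, obs, rcond=None)
    return float(beta0), float(beta1)


def accuracy(observed, predicted) -> tuple[float, float]:
    """(R^2, RMSE in kg/ha). R^2 is NaN when observed has zero variance."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length and nonempty")
    rmse = float(np.sqrt(mean_squared_error(obs, pred)))
    if np.ptp(obs) == 0:
        return float("nan"), rmse
    return float(r2_score(obs, pred)), rmse


def train_yield_model(features, yields, year: int = 0, seed: int = 0, n_trees: int = N_TREES, min_fields: int = MIN_TRAINING_FIELDS) -> YieldModel:
    """Fit both steps on one year's fields and report training-set metrics.

    Training-set accuracy is the conventional report when crop-cut samples
    are few; :func:`cross_validate` provides the honest generalization
    estimate alongside.
    """
    X = _as_feature_matrix(features)
    y = np.asarray(yields, dtype=float)
    rf = fit_rf_yield(X, y, seed=seed, n_trees=n_trees, min_fields=min_fields)
    raw = rf.predict(X)
    beta0, beta1 = fit_bias_correction(y, raw)
    corrected = beta0 + beta1 * raw
    r2, rmse = accuracy(y, corrected)
    dates = list(features.columns) if isinstance(features, pd.DataFrame) else list(range(X.shape[1]))
    return YieldModel(
        year=year,
        rf=rf,
        dates=dates,
        beta0=beta0,
        beta1=beta1,
        training_r2=r2,
        training_rmse=rmse,
        pbias_raw=pbias(y, raw),
    )


def cross_validate(
    features,
    yields,
    k: int = 5,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_trees: int = N_TREES,
    mode: str = "repeated",
    overfit_gap: float = 0.15,
) -> pd.DataFrame:
    """k repeated random train/test splits (default 70/30) of the two-step fit.

    ``mode="repeated"`` draws k independent splits at ``train_fraction``;
    ``mode="kfold"`` uses classic disjoint folds instead. Returns one row
    per repeat with train/test R^2 and RMSE; ``df.attrs`` carries the means
    and an ``overfitting`` flag set when mean train R^2 exceeds mean test
    R^2 by more than ``overfit_gap``.
    """
    X = _as_feature_matrix(features)
    y = np.asarray(yields, dtype=float)
    n_test = int(round(len(X) * (1 - train_fraction)))
    if n_test < 5:
        raise ValueError(f"test split of {n_test} fields is too small")
    if mode == "repeated":
        splitter = ShuffleSplit(n_splits=k, train_size=train_fraction, random_state=seed)
    elif mode == "kfold":
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown cross-validation mode {mode!r}")
    rows = []
    for rep, (tr, te) in enumerate(splitter.split(X)):
        model = train_yield_model(X[tr], y[tr], seed=seed + rep, n_trees=n_trees, min_fields=3)
        tr_r2, tr_rmse = accuracy(y[tr], model.predict_fields(X[tr]))
        te_r2, te_rmse = accuracy(y[te], model.predict_fields(X[te]))
        rows.append(
            {
                "repeat": rep,
                "n_train": len(tr),
                "n_test": len(te),
                "train_r2": tr_r2,
                "test_r2": te_r2,
                "train_rmse": tr_rmse,
                "test_rmse": te_rmse,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mean_train_r2"] = float(out["train_r2"].mean())
    out.attrs["mean_test_r2"] = float(out["test_r2"].mean())
    out.attrs["overfitting"] = bool(
        out.attrs["mean_train_r2"] - out.attrs["mean_test_r2"] > overfit_gap
    )
    return out


def predict_pixel_yields(model: YieldModel, stack: GCVIStack, cropland_mask) -> YieldRaster:
    """Apply the two-step estimator to every cropland pixel of a GCVI stack.

    Each pixel's multi-date GCVI vector goes through the forest, then the
    bias correction ``beta0 + beta1 * rf``, then a clamp at zero (negative
    corrected yields are not physical). Non-cropland pixels are NaN.
    """
    mask = np.asarray(cropland_mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("cropland mask shape does not match the GCVI stack")
    if list(stack.dates) != list(model.dates):
        missing = [d for d in model.dates if d not in stack.dates]
        extra = [d for d in stack.dates if d not in model.dates]
        raise ValueError(
            f"stack dates do not match training dates (missing {missing}, extra {extra})"
        )
    feats = stack.pixel_features()
    flat_mask = mask.ravel() & np.isfinite(feats).all(axis=1)
    values = np.full(flat_mask.shape, np.nan)
    if flat_mask.any():
        pred = model.rf.predict(feats[flat_mask])
        values[flat_mask] = np.clip(model.beta0 + model.beta1 * pred, 0.0, None)
    return YieldRaster(
        year=model.year,
        values=values.reshape(mask.shape),
        mask=mask,
        georef=stack.georef,
    )
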