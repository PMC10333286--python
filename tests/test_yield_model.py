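"""Two-step yield estimator: forest fit, bias correction, pixel prediction."""

import numpy as np
import pandas as pd
import pytest

from fieldgap import (
    GCVIStack,
    accuracy,
    cross_validate,
    extract_mean,
    fit_bias_correction,
    fit_rf_yield,
    pbias,
    predict_pixel_yields,
    train_yield_model,
)
from fieldgap.yield_model import YieldRaster


def monotone_dataset(n=300, noise=0.0, seed=0):
    """Yield as a noiseless monotone function of one dominant GCVI feature."""
    rng = np.random.default_rng(seed)
    g1 = rng.uniform(0.5, 3.0, n)
    g2 = rng.uniform(0.5, 3.0, n)
    X = np.column_stack([g1, g2])
    y = 800.0 * g1 + 100.0 + rng.normal(0, noise, n)
    return X, y


class TestPBias:
    def test_zero_when_equal(self, rng):
        obs = rng.uniform(1000, 3000, 50)
        assert pbias(obs, obs) == 0.0

    def test_ten_percent_overprediction(self, rng):
        obs = rng.uniform(1000, 3000, 50)
        assert pbias(obs, 1.1 * obs) == pytest.approx(10.0)

    def test_matches_direct_summation(self, rng):
        obs = rng.uniform(500, 4000, 200)
        pred = obs + rng.normal(0, 300, 200)
        expected = 100 * sum(p - o for o, p in zip(obs, pred)) / sum(obs)
        assert pbias(obs, pred) == pytest.approx(expected)

    def test_zero_observed_sum_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pbias([1.0, -1.0], [1.0, 1.0])


class TestBiasCorrection:
    def test_identity(self, rng):
        pred = rng.uniform(1000, 3000, 30)
        b0, b1 = fit_bias_correction(pred, pred)
        assert b0 == pytest.approx(0.0, abs=1e-9 * 3000)
        assert b1 == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear(self, rng):
        pred = rng.uniform(1000, 3000, 30)
        b0, b1 = fit_bias_correction(2 * pred + 100, pred)
        assert b0 == pytest.approx(100.0)
        assert b1 == pytest.approx(2.0)

    def test_matches_normal_equations(self, rng):
        """OLS coefficients equal the closed-form normal-equation solution."""
        pred = rng.uniform(1000, 3000, 100)
        obs = 0.8 * pred + 400 + rng.normal(0, 200, 100)
        b0, b1 = fit_bias_correction(obs, pred)
        sxx = np.sum((pred - pred.mean()) ** 2)
        sxy = np.sum((pred - pred.mean()) * (obs - obs.mean()))
        assert b1 == pytest.approx(sxy / sxx, rel=1e-9)
        assert b0 == pytest.approx(obs.mean() - (sxy / sxx) * pred.mean(), rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_bias_correction([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_corrected_pbias_is_zero(self, rng):
        """Two-step property: OLS residuals sum to zero, so PBIAS vanishes."""
        X, y = monotone_dataset(n=120, noise=200.0, seed=2)
        model = train_yield_model(X, y, seed=0, n_trees=100)
        corrected = model.predict_fields(X)
        assert abs(pbias(y, corrected)) < 1e-6


class TestAccuracy:
    def test_perfect(self, rng):
        obs = rng.uniform(0, 1, 20)
        assert accuracy(obs, obs) == (1.0, 0.0)

    def test_constant_prediction_r2_zero(self, rng):
        obs = rng.uniform(1000, 2000, 50)
        r2, rmse = accuracy(obs, np.full(50, obs.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert rmse == pytest.approx(obs.std())

    def test_matches_definitions(self, rng):
        obs = rng.uniform(0, 10, 100)
        pred = obs + rng.normal(0, 1, 100)
        r2, rmse = accuracy(obs, pred)
        assert rmse == pytest.approx(np.sqrt(np.mean((obs - pred) ** 2)))
        assert r2 == pytest.approx(1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))

    def test_zero_variance_flagged(self):
        r2, rmse = accuracy([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(r2) and rmse == 1.0


class TestFitRF:
    def test_noiseless_monotone_high_heldout_r2(self):
        X, y = monotone_dataset(n=300, seed=1)
        rf = fit_rf_yield(X[:210], y[:210], seed=0, n_trees=200)
        r2, _ = accuracy(y[210:], rf.predict(X[210:]))
        assert r2 > 0.9

    def test_permutation_null_no_spurious_skill(self):
        """Permuted labels: held-out R^2 shows no skill (mean < 0.1).

        The mean sits slightly below zero rather than at it — a forest fit
        to pure noise keeps prediction variance that inflates test error —
        so the check is one-sided, against spurious positive skill.
        """
        r2s = []
        for rep in range(20):
            X, y = monotone_dataset(n=120, seed=rep)
            rng = np.random.default_rng(rep)
            y_perm = rng.permutation(y)
            rf = fit_rf_yield(X[:80], y_perm[:80], seed=rep, n_trees=60)
            r2, _ = accuracy(y_perm[80:], rf.predict(X[80:]))
            r2s.append(r2)
        assert np.mean(r2s) < 0.1

    def test_constant_target(self, rng):
        X = rng.uniform(0, 3, (30, 2))
        rf = fit_rf_yield(X, np.full(30, 2500.0), seed=0, n_trees=20)
        np.testing.assert_allclose(rf.predict(X), 2500.0)

    def test_too_few_fields_rejected(self, rng):
        with pytest.raises(ValueError, match="training fields"):
            fit_rf_yield(rng.uniform(0, 1, (10, 3)), rng.uniform(0, 1, 10))

    def test_missing_features_rejected(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        X[4, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_rf_yield(X, rng.uniform(0, 1, 30))


class TestCrossValidate:
    def test_split_sizes_and_determinism(self):
        X, y = monotone_dataset(n=100, noise=100.0, seed=3)
        cv1 = cross_validate(X, y, k=5, train_fraction=0.7, seed=9, n_trees=30)
        cv2 = cross_validate(X, y, k=5, train_fraction=0.7, seed=9, n_trees=30)
        assert (cv1["n_train"] == 70).all() and (cv1["n_test"] == 30).all()
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_noiseless_no_overfit(self):
        X, y = monotone_dataset(n=200, seed=4)
        cv = cross_validate(X, y, k=5, seed=0, n_trees=150)
        assert abs(cv.attrs["mean_train_r2"] - cv.attrs["mean_test_r2"]) < 0.1
        assert not cv.attrs["overfitting"]

    def test_kfold_mode(self):
        X, y = monotone_dataset(n=100, noise=100.0, seed=5)
        cv = cross_validate(X, y, k=5, seed=0, n_trees=30, mode="kfold")
        assert cv["n_test"].sum() == 100


def uniform_stack(feature_vec, shape=(8, 8), dates=(20, 60, 95, 130)):
    layers = np.stack([np.full(shape, v) for v in feature_vec])
    return GCVIStack(dates=list(dates), layers=layers)


class TestPredictPixelYields:
    def _model(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.3, 3.0, (60, 4))
        y = 900 * X[:, 2] + 200 + rng.normal(0, 100, 60)
        feats = pd.DataFrame(X, columns=[20, 60, 95, 130])
        return train_yield_model(feats, y, seed=seed, n_trees=80), X, y

    def test_uniform_stack_equals_field_prediction(self):
        model, X, _ = self._model()
        stack = uniform_stack(X[7])
        raster = predict_pixel_yields(model, stack, np.ones((8, 8), dtype=bool))
        expected = model.predict_fields(X[7][None, :])[0]
        np.testing.assert_allclose(raster.values, max(expected, 0.0))

    def test_identity_correction_equals_raw_rf(self):
        model, X, _ = self._model()
        model.beta0, model.beta1 = 0.0, 1.0
        stack = uniform_stack(X[3])
        raster = predict_pixel_yields(model, stack, np.ones((8, 8), dtype=bool))
        np.testing.assert_allclose(raster.values, model.rf.predict(X[3][None, :])[0])

    def test_matches_pixelwise_loop(self, rng):
        model, _, _ = self._model(seed=6)
        layers = rng.uniform(0.3, 3.0, (4, 8, 8))
        stack = GCVIStack(dates=[20, 60, 95, 130], layers=layers)
        mask = rng.uniform(size=(8, 8)) < 0.7
        raster = predict_pixel_yields(model, stack, mask)
        for r in range(8):
            for c in range(8):
                if mask[r, c]:
                    vec = layers[:, r, c][None, :]
                    exp = model.beta0 + model.beta1 * model.rf.predict(vec)[0]
                    assert raster.values[r, c] == pytest.approx(max(exp, 0.0))
                else:
                    assert np.isnan(raster.values[r, c])

    def test_date_mismatch_rejected(self):
        model, X, _ = self._model()
        stack = GCVIStack(dates=[20, 60, 95], layers=np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="dates"):
            predict_pixel_yields(model, stack, np.ones((4, 4), dtype=bool))

    def test_field_round_trip_through_raster(self):
        """extract_mean over the yield raster recovers the tabular prediction
        exactly when all of a field's pixels share one GCVI vector."""
        from fieldgap import GridGeoref
        from shapely.geometry import Polygon

        model, X, _ = self._model(seed=8)
        stack = uniform_stack(X[11])
        stack.georef = GridGeoref(0.0, 8.0, 1.0)
        raster = predict_pixel_yields(model, stack, np.ones((8, 8), dtype=bool))
        poly = Polygon([(1, 1), (7, 1), (7, 7), (1, 7)])
        got = extract_mean(raster.values, stack.georef, poly)
        expected = model.predict_fields(X[11][None, :])[0]
        assert got == pytest.approx(max(expected, 0.0))


def test_two_step_recovery_rmse_within_noise():
    """With 150 kg/ha crop-cut noise and n=300, field-level RMSE of the
    two-step estimator stays below twice the measurement noise."""
    from fieldgap import generate_landscape, SyntheticConfig
    from fieldgap.preprocess import compute_gcvi
    from fieldgap.geodata import extract_means

    cfg = SyntheticConfig(
        n_fields=300, n_years=2, grid_shape=(160, 160), noise_sd_cropcut=150.0, seed=21
    )
    scenes, fields, mask, truth = generate_landscape(cfg)
    polys = [f.polygon for f in fields]
    feats = np.column_stack(
        [extract_means(compute_gcvi(sc), truth.georef, polys) for sc in scenes[0]]
    )
    cuts = np.array([f.crop_cuts[0] for f in fields])
    model = train_yield_model(feats, cuts, seed=0, n_trees=200)
    true0 = truth.field_years.query("year == 0")["true_yield"].to_numpy()
    rmse = float(np.sqrt(np.mean((model.predict_fields(feats) - true0) ** 2)))
    assert rmse <= 2 * 150.0
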