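"""Driver forest, out-of-bag %IncMSE importance, partial dependence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import r2_score

from fieldgap import (
    DRIVER_PREDICTORS,
    fit_driver_rf,
    optimal_management,
    partial_dependence,
    variable_importance,
)
from fieldgap.drivers import PDPCurve, oob_predict


def driver_frame(n=300, seed=0, yg_fn=None):
    """Random covariates in realistic ranges; response from yg_fn(frame)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "dos": rng.integers(0, 61, n).astype(float),
            "irrigations": rng.integers(1, 4, n).astype(float),
            "avg_temp_c": rng.normal(22, 1.2, n),
            "total_rain_mm": rng.uniform(0, 120, n),
            "nitrogen_cgkg": rng.normal(80, 15, n),
            "soc_dgkg": rng.normal(60, 12, n),
            "plot_area_ha": rng.uniform(0.1, 0.5, n),
        }
    )
    df["yg"] = yg_fn(df, rng) if yg_fn else rng.normal(1000, 300, n)
    return df


def dos_driven(df, rng, noise=0.0):
    return 20.0 * df["dos"] + 500 + rng.normal(0, noise, len(df))


class TestFitDriverRF:
    def test_oob_predictions_match_sklearn_oob_score(self):
        """The reconstructed per-tree bootstrap must reproduce oob_score_ exactly."""
        df = driver_frame(200, seed=1, yg_fn=lambda d, r: dos_driven(d, r, 200.0))
        rf = fit_driver_rf(df, seed=3, n_trees=120)
        mine = r2_score(df["yg"], oob_predict(rf, df[list(DRIVER_PREDICTORS)].to_numpy()))
        assert mine == pytest.approx(rf.oob_score_, abs=1e-12)

    def test_noiseless_dos_function_high_oob_r2(self):
        df = driver_frame(500, seed=2, yg_fn=dos_driven)
        rf = fit_driver_rf(df, seed=0, n_trees=200)
        assert rf.oob_score_ > 0.8

    def test_pure_noise_no_skill(self):
        scores = []
        for seed in range(20):
            df = driver_frame(100, seed=seed)
            rf = fit_driver_rf(df, seed=seed, n_trees=60)
            scores.append(rf.oob_score_)
        assert np.mean(scores) <= 0.1

    def test_constant_response(self):
        df = driver_frame(50, seed=3, yg_fn=lambda d, r: np.full(len(d), 900.0))
        rf = fit_driver_rf(df, seed=0, n_trees=30)
        np.testing.assert_allclose(
            rf.predict(df[list(DRIVER_PREDICTORS)].to_numpy()), 900.0
        )

    def test_missing_predictor_named(self):
        df = driver_frame(60, seed=4).drop(columns=["soc_dgkg"])
        with pytest.raises(ValueError, match="soc_dgkg"):
            fit_driver_rf(df)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="rows"):
            fit_driver_rf(driver_frame(10, seed=5))


class TestVariableImportance:
    def test_constant_column_near_zero(self):
        df = driver_frame(200, seed=6, yg_fn=lambda d, r: dos_driven(d, r, 100.0))
        df["nitrogen_cgkg"] = 80.0  # constant: permuting it changes nothing
        rf = fit_driver_rf(df, seed=0, n_trees=100)
        imp = variable_importance(rf, n_permutations=3, seed=0)
        val = imp.set_index("predictor").loc["nitrogen_cgkg", "pct_inc_mse"]
        assert abs(val) < 1.0

    def test_dominant_dos_ranks_first(self):
        wins = 0
        for seed in range(10):
            df = driver_frame(250, seed=seed, yg_fn=lambda d, r: dos_driven(d, r, 150.0))
            rf = fit_driver_rf(df, seed=seed, n_trees=150)
            imp = variable_importance(rf, n_permutations=2, seed=seed)
            wins += imp["predictor"].iloc[0] == "dos"
        assert wins >= 9

    def test_duplicated_noise_column_in_noise_band(self):
        """An irrelevant column and its duplicate get indistinguishable importance."""
        df = driver_frame(250, seed=9, yg_fn=lambda d, r: dos_driven(d, r, 150.0))
        rng = np.random.default_rng(0)
        df["noise_a"] = rng.normal(size=len(df))
        df["noise_b"] = df["noise_a"] + 0.0
        preds = list(DRIVER_PREDICTORS) + ["noise_a", "noise_b"]
        rf = fit_driver_rf(df, seed=0, n_trees=200, predictors=preds)
        imp = variable_importance(rf, n_permutations=5, seed=1).set_index("predictor")
        a, b = imp.loc["noise_a", "pct_inc_mse"], imp.loc["noise_b", "pct_inc_mse"]
        assert abs(a - b) < 2.0 and abs(a) < 3.0 and abs(b) < 3.0

    def test_ranks_are_permutation(self):
        df = driver_frame(100, seed=10, yg_fn=lambda d, r: dos_driven(d, r, 300.0))
        rf = fit_driver_rf(df, seed=0, n_trees=80)
        imp = variable_importance(rf, n_permutations=2, seed=0)
        assert sorted(imp["rank"]) == list(range(1, 8))


class TestPartialDependence:
    def test_irrelevant_predictor_flat_curve(self):
        df = driver_frame(300, seed=11, yg_fn=dos_driven)
        rf = fit_driver_rf(df, seed=0, n_trees=150)
        pdp = partial_dependence(rf, df, "soc_dgkg")
        assert np.ptp(pdp.values) < 0.05 * np.ptp(df["yg"])

    def test_additive_model_recovered_up_to_shift(self):
        """YG = g(DOS) + h(rain): the DOS PDP equals g up to a constant."""
        g = lambda dos: 15.0 * dos + 2.0 * (dos - 30) ** 2 / 10
        df = driver_frame(
            500, seed=12, yg_fn=lambda d, r: g(d["dos"]) + 5.0 * d["total_rain_mm"]
        )
        rf = fit_driver_rf(df, seed=0, n_trees=300)
        grid = np.arange(5, 56, dtype=float)
        pdp = partial_dependence(rf, df, "dos", grid=grid)
        target = g(grid)
        dev = (pdp.values - target) - (pdp.values - target).mean()
        assert np.sqrt(np.mean(dev**2)) < 0.10 * np.ptp(target)

    def test_single_point_grid(self):
        df = driver_frame(100, seed=13, yg_fn=lambda d, r: dos_driven(d, r, 100.0))
        rf = fit_driver_rf(df, seed=0, n_trees=60)
        pdp = partial_dependence(rf, df, "dos", grid=[30.0])
        X = df[list(DRIVER_PREDICTORS)].to_numpy().copy()
        X[:, 0] = 30.0
        assert pdp.values[0] == pytest.approx(rf.predict(X).mean())

    def test_grid_outside_range_rejected(self):
        df = driver_frame(100, seed=14)
        rf = fit_driver_rf(df, seed=0, n_trees=40)
        with pytest.raises(ValueError, match="range"):
            partial_dependence(rf, df, "dos", grid=[-5.0, 30.0, 200.0])

    def test_centering_property(self):
        """PDP averaged over the empirical predictor values ~ mean prediction."""
        df = driver_frame(300, seed=15, yg_fn=lambda d, r: dos_driven(d, r, 200.0))
        rf = fit_driver_rf(df, seed=0, n_trees=150)
        grid = np.sort(df["dos"].unique())
        pdp = partial_dependence(rf, df, "dos", grid=grid)
        weights = df["dos"].value_counts().sort_index().to_numpy()
        pdp_mean = np.average(pdp.values, weights=weights)
        overall = rf.predict(df[list(DRIVER_PREDICTORS)].to_numpy()).mean()
        assert pdp_mean == pytest.approx(overall, rel=0.02)

    def test_slope_signs_match_generating_effects(self):
        df = driver_frame(
            400,
            seed=16,
            yg_fn=lambda d, r: 20.0 * d["dos"] - 150.0 * d["irrigations"] + r.normal(0, 100, len(d)),
        )
        rf = fit_driver_rf(df, seed=0, n_trees=200)
        pdp_dos = partial_dependence(rf, df, "dos")
        pdp_irr = partial_dependence(rf, df, "irrigations")
        assert pdp_dos.values[-1] > pdp_dos.values[0]  # later sowing -> bigger gap
        assert pdp_irr.values[-1] < pdp_irr.values[0]  # more water -> smaller gap


class TestOptimalManagement:
    def test_monotone_curves(self):
        pdp_dos = PDPCurve("dos", np.arange(0, 30.0), np.arange(0, 30.0) * 10 + 500)
        pdp_irr = PDPCurve("irrigations", [1.0, 2.0, 3.0], [900.0, 700.0, 500.0])
        dos_star, irrig_star = optimal_management(pdp_dos, pdp_irr)
        assert dos_star == 0.0 and irrig_star == 3.0

    def test_interior_minimum_recovered(self):
        grid = np.arange(0, 61.0)
        vals = (grid - 11.0) ** 2 + 300.0  # planted optimum at day 11
        pdp_dos = PDPCurve("dos", grid, vals)
        pdp_irr = PDPCurve("irrigations", [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        dos_star, irrig_star = optimal_management(pdp_dos, pdp_irr)
        assert dos_star == 11.0
        assert irrig_star == 3.0  # ties break toward more irrigations

    def test_dos_ties_break_earlier(self):
        pdp_dos = PDPCurve("dos", [0.0, 10.0, 20.0], [5.0, 5.0, 9.0])
        pdp_irr = PDPCurve("irrigations", [1.0], [1.0])
        assert optimal_management(pdp_dos, pdp_irr)[0] == 0.0
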