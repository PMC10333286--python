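"""Two-step satellite yield estimation: random forest + bias correction.

Per-field mean GCVI at each scene date feeds a random-forest regression
against crop-cut yields; the forest's predictions are then linearly
re-calibrated against the observations (OLS), which removes the forest's
systematic shrinkage toward the training mean (nonzero percent bias).
"""

import numpy as np
import pandas as pd

from fieldgap import (
    SyntheticConfig,
    cross_validate,
    generate_landscape,
    compute_gcvi,
    pbias,
    predict_pixel_yields,
    train_yield_model,
)
from fieldgap.geodata import extract_means
from fieldgap.preprocess import GCVIStack

cfg = SyntheticConfig(n_fields=150, n_years=2, grid_shape=(112, 112), seed=7)
scenes, fields, mask, truth = generate_landscape(cfg)
polys = [f.polygon for f in fields]

year = 0
dates = [sc.date for sc in scenes[year]]
layers = [compute_gcvi(sc) for sc in scenes[year]]
features = pd.DataFrame(
    np.column_stack([extract_means(g, truth.georef, polys) for g in layers]),
    columns=dates,
)
cuts = np.array([f.crop_cuts[year] for f in fields])

model = train_yield_model(features, cuts, year=year, seed=0)
print(f"step 1 (forest) percent bias: {model.pbias_raw:+.1f}%")
print(f"step 2 (OLS): beta0 = {model.beta0:.0f} kg/ha, beta1 = {model.beta1:.2f}")
print(f"corrected percent bias: {pbias(cuts, model.predict_fields(features)):+.2e}%")
print(f"training accuracy: R2 = {model.training_r2:.2f}, "
      f"RMSE = {model.training_rmse:.0f} kg/ha")

cv = cross_validate(features, cuts, k=5, train_fraction=0.7, seed=0)
print(f"5 x 70/30 split validation: train R2 {cv.attrs['mean_train_r2']:.2f}, "
      f"test R2 {cv.attrs['mean_test_r2']:.2f} "
      f"(overfitting flag: {cv.attrs['overfitting']})")

stack = GCVIStack(dates=dates,
                  layers=np.stack(layers), georef=truth.georef)
raster = predict_pixel_yields(model, stack, mask)
vals = raster.masked_values()
print(f"pixel yield map: {vals.size} cropland pixels, "
      f"mean {vals.mean():.0f} kg/ha, 95th percentile {np.percentile(vals, 95):.0f} kg/ha")
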