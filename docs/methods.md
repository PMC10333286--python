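# Methods

`fieldgap` implements a complete field-level yield-gap analysis for
smallholder wheat landscapes of the kind found in the eastern
Indo-Gangetic Plains: satellite-style yield estimation from multi-date
vegetation-index stacks, empirical yield-potential and yield-gap
quantification, yield-persistence statistics, driver attribution, and
ideal-management counterfactuals. Because the field and imagery data such
studies rest on are essentially never released, the package ships a
synthetic landscape generator with known ground truth; every stage is
validated by recovering quantities the generator knows exactly.

## The synthetic landscape

The generator (`fieldgap.synth`) states a world and sticks to it. True
yield of field *i* in season *y* is linear in its drivers:

```
Y_iy = base + b_dos·DOS_i + b_irr·Irrig_i + b_T·(T_y − T̄) + b_R·(R_y − R̄)
     + b_A·Area_i + f_i + e_iy,   clamped at 0
```

with a persistent field intercept `f_i ~ N(0, field_effect_sd²)` and a
season shock `e_iy ~ N(0, noise_sd_yield²)`. Crop-cut observations add
independent Gaussian measurement error (`noise_sd_cropcut`); additive
Gaussian noise is a modelling choice — the error structure of real crop
cuts is not identified by any data we hold.

Defaults (units kg/ha unless noted) and why:

| parameter | default | rationale |
|---|---|---|
| `base_yield` | 2600 | puts mean yields near 2.3 t/ha, typical of rabi wheat in Bihar |
| `effect_dos` | −20 /day | later sowing pushes grain filling into terminal heat; tens of kg/ha/day is the agronomic consensus range |
| `effect_irrigation` | +150 /application | 1→3 irrigations spans ~300 kg/ha in a groundwater-constrained system |
| `effect_temp` | −150 /°C | warm winters shorten the grain-filling window |
| `effect_rain` | +1.5 /mm | rabi is dry; rainfall helps marginally |
| `effect_area` | +300 /ha | plot area proxies wealth/management quality |
| `field_effect_sd` | 250 | persistent soil/skill differences across fields |
| `noise_sd_yield` | 300 | year-specific shocks (pests, lodging, micro-weather) |
| `noise_sd_cropcut` | 150 | subplot sampling + weighing error |
| `n_fields`, `n_years` | 271, 5 | the scale of the emulated survey |
| scene dates | 20, 60, 95, 130 days after Nov 1 | early vegetative, tillering, peak greenness, senescence |

Sowing dates are uniform over days 0–60 after Nov 1 (early November to
early January), irrigations uniform on {1, 2, 3}, plots 0.16–0.49 ha
(smallholder scale), soil nitrogen ~ N(80, 15) cg/kg and organic carbon
~ N(60, 12) dg/kg (plausible WoSIS-like magnitudes; soil is deliberately
*not* wired into the yield equation, so soil importance under the default
world is a null check). Weather varies by year only, emulating the coarse
resolution of gridded climate products relative to an 8 × 16 km site.

Per-pixel GCVI follows an asymmetric-Gaussian phenology (peak near day
95, green-up σ = 32 d, senescence σ = 22 d) whose amplitude is strictly
increasing in true yield; green and NIR bands are constructed so that
`NIR/green − 1` reproduces the intended GCVI exactly. Non-cropland pixels
get a constant low GCVI. Fields are axis-aligned rectangles on a
non-overlapping block grid — irregular polygon shapes add nothing the
zonal statistics can be tested on. Background cropland pixels (to reach
`crop_fraction`) behave like unsampled fields drawn from the same yield
model, so the pixel-level yield distribution that defines yield potential
is continuous with the surveyed fields.

**What a green test does and does not establish.** The generator omits
clouds, atmospheric effects, sensor noise, mixed pixels at field edges,
GPS error, within-field yield variability and management that varies by
year. Green tests establish that the estimators recover a known world
when their assumptions hold and that all contracts and identities are
implemented correctly — not that the pipeline is robust to the
pathologies of real imagery.

## Yield estimation

GCVI = NIR/green − 1 per scene; per-field features are the polygon-mean
GCVI per scene date (mean over pixels whose centers fall inside the
polygon — deterministic, and negligible against area-weighting for fields
of ≥ 30 pixels). Top-of-atmosphere scenes can be harmonised by
histogram matching: each band is remapped through the blended quantile
function `Q_mix(p) = w1·Q_before(p) + w2·Q_after(p)` of two bracketing
reference scenes, with inverse day-gap weights. Blending quantile
functions (not densities) is our concrete reading of a "date-weighted
average of histograms": it keeps the remapping monotone, hence
rank-preserving. The one-vs-two-reference day threshold is exposed as a
caller decision, including the tie at exactly two days.

The estimator is two-step and fitted per season, never pooled:

1. random-forest regression of crop-cut yield on the per-date GCVI
   vector (500 trees, default feature subsampling, fixed seed —
   hyperparameters are unstated in the literature this emulates, so we
   pin conventional ones);
2. OLS of observed yield on the forest prediction. Forest predictions
   shrink toward the training mean, so their percent bias
   `100·Σ(pred−obs)/Σ(obs)` is nonzero; the OLS recalibration drives the
   training-set PBIAS to zero exactly (residuals of an OLS fit with
   intercept sum to zero).

The fitted (β0, β1) are applied to every cropland pixel's forest
prediction, clamped at zero (the data cannot support negative yields;
the clamp is at the pixel scale only). Validation reports training-set
R²/RMSE — the convention when crop cuts are scarce — alongside
repeated-split validation as the honest generalization estimate.
"Five-fold cross-validation with 70/30 splits" is internally inconsistent
with disjoint folds; we implement 5 repeated random 70/30 splits by
default and expose classic k-fold as `mode="kfold"`.

A caveat the tests encode: a forest fit to permuted labels has *negative*
expected held-out R² (its predictions retain variance with no signal), so
null checks are one-sided — no spurious positive skill — rather than
|R²| ≈ 0.

## Yield potential, gaps, persistence

Yield potential `Yp_y` is the 95th percentile (linear interpolation
between order statistics — pinned because conventions differ) of the
season's cropland pixel-yield distribution; an economically achievable
ceiling, not a crop-model potential. Yield gap `YG_iy = Yp_y − Ymean_iy`
per field, negatives retained (clamping would bias mean gaps upward).
Per-year summaries average over fields, not pixels, with a
normal-approximation 95% CI.

Persistence is measured two ways on a field-by-year panel of satellite
yields. (1) Decile analysis: fields ranked by base-year yield into ten
near-equal groups (stable ties, larger groups first); the distribution of
each group's yields pooled over later seasons is summarised with
five-number statistics plus an adjacent-IQR-overlap diagnostic.
(2) Anomaly persistence: `100 · A_later / A_base`, where `A_base` is the
top decile's mean anomaly from the base-year site mean and `A_later` the
same fields' mean anomaly from each later season's site mean, field-years
equally weighted. Anomalies are absolute (kg/ha) — relative anomalies are
available as a switch but not the default — and each year's site mean is
computed over the tracked fields, keeping the statistic self-contained.
Per-year additive shifts cancel exactly.

## Driver attribution and scenarios

A pooled random forest regresses YG on seven drivers (sowing date,
irrigations, season mean temperature, season rainfall, soil N, soil
organic C, plot area); year-varying predictors carry the year
information, and a per-year fit is available. Importance is %IncMSE on
out-of-bag (OOB) predictions: permute one column, recompute the OOB MSE,
report the mean percent increase over permutations. scikit-learn does not
expose per-tree OOB membership, so the bootstrap indices are regenerated
from each tree's `random_state` by the same draw sklearn uses; a test
pins the reconstruction against `oob_score_` to machine precision, so any
upstream change breaks loudly. Partial dependence is the standard
marginal average over the data with one predictor pinned to each grid
value (integer days for sowing date, observed counts for irrigation).

The ideal-management scenario overrides sowing date and/or irrigations
with the PDP minimisers (ties toward earlier sowing, more irrigation) and
re-predicts YG. Since Yp is fixed within a season, a predicted gap
reduction is exactly a yield gain; predicting in YG space avoids
refitting a separate yield model. The per-field gain is measured against
the model's own baseline prediction (so a no-op override gives exactly
zero), while the closure percent divides by the *observed* mean gap of
the same rows. Overrides are clipped to the training support — forests
extrapolate poorly. The generator's linearity makes the true closure
fraction analytic (`truth_closure_fraction`), which is the recovery
target: across 20 replicates at 300 fields the median relative error of
the estimated ideal-both closure is required to stay under 20%. The
forest attenuates management effects in proportion to the unexplained
(field-effect + shock) variance, which is why heavy-noise worlds recover
closures less sharply; this is a property of the estimator, not a bug.

## Numerical choices and degenerate inputs

- GCVI at green = 0 is NaN and propagates through zonal means (excluded)
  and pixel predictions (pixel left missing).
- Zonal mean of a polygon containing no finite pixel center returns NaN
  with a warning, never an exception; empty cropland masks, constant RF
  predictors, < 3 bias-correction points, < 10 fields for deciles, and a
  non-positive top-decile base anomaly are rejected with named errors.
- Corner points are ordered by angle about their centroid; duplicate or
  three-collinear corners raise a degenerate-geometry error. The surveyed
  center point is used only to validate (it must lie inside the ring).
- Determinism: one `numpy` Generator seeded from the config drives all
  randomness; scene rendering consumes no random numbers, so skipping it
  changes nothing downstream. Pipeline reruns with one config + seed are
  byte-identical at the CSV level.
- Rasters are stored as multi-band TIFF with a YAML sidecar for
  georeferencing (GDAL-free environments read them anywhere); geometry
  lives in a projected metric CRS throughout.

## Known limitations

- The two-step estimator is only as good as the GCVI–yield coupling; the
  generator's coupling is exact and noiseless within fields, so real-world
  accuracies will be lower than synthetic ones.
- %IncMSE inherits permutation importance's known bias under correlated
  predictors; the default world keeps drivers independent, so ranks are
  clean there but should be read cautiously on real data.
- Scenario closures are associational: the driver forest is fitted to
  observational variation, and the counterfactual assumes the fitted
  response transfers to intervened management.
- The persistence percent compares one base year against pooled later
  years; it does not decompose persistence by horizon.
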