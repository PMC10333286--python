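"""Synthetic smallholder wheat landscape with known ground truth.

Generates everything the analysis chain consumes — multi-date multi-band
scenes, field polygons, crop-cut / management / environment tables, and a
cropland mask — from a small set of named effect sizes, so that every
downstream stage (yield model, yield gaps, persistence, drivers,
scenarios) can be checked against analytically known answers.

The generating model for the true yield of field *i* in year *y* is linear:

    Y_iy = base + b_dos * DOS_i + b_irr * Irrig_i
         + b_T * (T_y - mean(T)) + b_R * (R_y - mean(R))
         + b_A * area_i + f_i + e_iy,     clamped at 0,

with a persistent field intercept ``f_i ~ N(0, field_effect_sd^2)`` and a
year-specific shock ``e_iy ~ N(0, noise_sd_yield^2)``. Crop-cut yields add
independent measurement noise ``N(0, noise_sd_cropcut^2)``. Per-pixel GCVI
follows a smooth asymmetric-Gaussian phenology whose peak amplitude is
strictly increasing in true yield; the green and NIR bands are constructed
so that ``NIR/green - 1`` reproduces that GCVI exactly. Non-cropland
pixels get a low, yield-independent GCVI.

Default parameter values describe a plausible Indo-Gangetic-Plains rabi
wheat season: ~2.3 t/ha mean yields, sowing spread over November–December,
1–3 irrigations, sub-0.5 ha plots, a dry cool winter.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .georef import GridGeoref
from .preprocess import SpectralScene

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "FieldRecord",
    "generate_landscape",
    "truth_ideal_gains",
    "truth_closure_fraction",
    "peak_gcvi",
    "SEASON_LENGTH_DAYS",
]

#: Days from Nov 1 to Apr 15, the rabi wheat season span.
SEASON_LENGTH_DAYS = 165

# Phenology constants: peak greenness near day 95 (early February), slower
# green-up than senescence, background GCVI floor for bare/early canopy.
_PEAK_DAY = 95.0
_SIGMA_RISE = 32.0
_SIGMA_FALL = 22.0
_GCVI_FLOOR = 0.15
_GCVI_AMP_BASE = 0.25
_GCVI_AMP_PER_KG = 6.0e-4
_NONCROP_GCVI = 0.18
_GREEN_REFLECTANCE = 0.08

_FIELD_BLOCK = 8  # pixels; each field lives inside one block of the layout grid


@dataclass
class SyntheticConfig:
    """Parameters of the generated landscape; defaults are the stated world."""

    n_fields: int = 271
    n_years: int = 5
    scene_dates_per_year: Sequence[int] = (20, 60, 95, 130)
    grid_shape: tuple = (144, 160)
    pixel_size: float = 10.0
    crop_fraction: float = 0.8
    effect_dos: float = -20.0  # kg/ha per day of sowing delay
    effect_irrigation: float = 150.0  # kg/ha per additional irrigation
    effect_temp: float = -150.0  # kg/ha per deg C (terminal heat stress)
    effect_rain: float = 1.5  # kg/ha per mm
    effect_area: float = 300.0  # kg/ha per ha
    field_effect_sd: float = 250.0
    noise_sd_yield: float = 300.0
    noise_sd_cropcut: float = 150.0
    base_yield: float = 2600.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fields < 20:
            raise ValueError(f"n_fields must be >= 20, got {self.n_fields}")
        if self.n_years < 2:
            raise ValueError(f"n_years must be >= 2, got {self.n_years}")
        dates = list(self.scene_dates_per_year)
        if not dates or any(d < 0 or d > SEASON_LENGTH_DAYS for d in dates):
            raise ValueError(
                "scene_dates_per_year must be non-empty days within "
                f"[0, {SEASON_LENGTH_DAYS}], got {dates}"
            )
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("scene_dates_per_year must be strictly increasing")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < _FIELD_BLOCK:
            raise ValueError(f"grid_shape must be (rows, cols) >= {_FIELD_BLOCK}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not (0 < self.crop_fraction <= 1):
            raise ValueError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")
        for name in ("field_effect_sd", "noise_sd_yield", "noise_sd_cropcut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        n_blocks = (self.grid_shape[0] // _FIELD_BLOCK) * (
            self.grid_shape[1] // _FIELD_BLOCK
        )
        if n_blocks < self.n_fields:
            raise ValueError(
                f"grid_shape {self.grid_shape} fits only {n_blocks} fields; "
                f"n_fields={self.n_fields} requires a larger grid"
            )


@dataclass
class FieldRecord:
    """One surveyed field: polygon geometry plus per-year yields and covariates."""

    field_id: int
    polygon: Polygon
    center: Point
    covariates: dict  # dos, irrigations, plot_area_ha, nitrogen_cgkg, soc_dgkg
    crop_cuts: dict  # year -> crop-cut yield kg/ha


@dataclass
class GroundTruth:
    """Everything the generator knows; the oracle for recovery tests."""

    config: SyntheticConfig
    fields: pd.DataFrame  # field_id, dos, irrigations, plot_area_ha, nitrogen, soc, field_effect
    years: pd.DataFrame  # year, avg_temp_c, total_rain_mm, yp_true
    field_years: pd.DataFrame  # field_id, year, true_yield, yield_kgha (crop cut)
    pixel_truth: np.ndarray  # (n_years, rows, cols) true yield, NaN off-cropland
    georef: GridGeoref = dc_field(default=None)

    def table(self) -> pd.DataFrame:
        """Flat field-year table with management and environment covariates."""
        out = self.field_years.merge(self.fields, on="field_id").merge(
            self.years.drop(columns=["yp_true"]), on="year"
        )
        return out.sort_values(["field_id", "year"]).reset_index(drop=True)


def _season_curve(day: float) -> float:
    sigma = _SIGMA_RISE if day <= _PEAK_DAY else _SIGMA_FALL
    return float(np.exp(-((day - _PEAK_DAY) ** 2) / (2 * sigma**2)))


def peak_gcvi(true_yield):
    """Peak-of-season GCVI implied by a true yield (strictly increasing)."""
    return _GCVI_FLOOR + _GCVI_AMP_BASE + _GCVI_AMP_PER_KG * np.asarray(true_yield)


def _gcvi_at(day: float, true_yield: np.ndarray) -> np.ndarray:
    amp = _GCVI_AMP_BASE + _GCVI_AMP_PER_KG * true_yield
    return _GCVI_FLOOR + amp * _season_curve(day)


def _place_fields(cfg: SyntheticConfig, rng: np.random.Generator):
    """Assign each field a rectangle of pixels inside its own layout block."""
    rows_b = cfg.grid_shape[0] // _FIELD_BLOCK
    cols_b = cfg.grid_shape[1] // _FIELD_BLOCK
    blocks = rng.permutation(rows_b * cols_b)[: cfg.n_fields]
    rects = []
    for b in blocks:
        br, bc = divmod(int(b), cols_b)
        h = int(rng.integers(4, _FIELD_BLOCK))
        w = int(rng.integers(4, _FIELD_BLOCK))
        r0 = br * _FIELD_BLOCK + int(rng.integers(0, _FIELD_BLOCK - h + 1))
        c0 = bc * _FIELD_BLOCK + int(rng.integers(0, _FIELD_BLOCK - w + 1))
        rects.append((r0, c0, h, w))
    return rects


def generate_landscape(config: SyntheticConfig, render_scenes: bool = True):
    """Generate scenes, field records, cropland mask and ground truth.

    Returns
    -------
    scenes : dict year -> list[SpectralScene], or None if ``render_scenes`` is False
    fields : list[FieldRecord]
    cropland_mask : bool array (rows, cols)
    truth : GroundTruth

    The same config (and seed) always produces bit-identical outputs;
    skipping scene rendering does not change any table or the mask.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    georef = GridGeoref(0.0, rows * cfg.pixel_size, cfg.pixel_size)

    rects = _place_fields(cfg, rng)
    field_ids = np.arange(cfg.n_fields)
    dos = rng.integers(0, 61, cfg.n_fields)  # early Nov .. early Jan
    irrig = rng.integers(1, 4, cfg.n_fields)
    nitrogen = rng.normal(80.0, 15.0, cfg.n_fields)
    soc = rng.normal(60.0, 12.0, cfg.n_fields)
    field_effect = rng.normal(0.0, cfg.field_effect_sd, cfg.n_fields)
    area_ha = np.array(
        [h * w * cfg.pixel_size**2 / 1e4 for (_, _, h, w) in rects]
    )

    years = np.arange(cfg.n_years)
    avg_temp = rng.normal(22.0, 1.2, cfg.n_years)
    total_rain = np.clip(rng.normal(60.0, 25.0, cfg.n_years), 0.0, None)
    t_dev = avg_temp - avg_temp.mean()
    r_dev = total_rain - total_rain.mean()

    def yield_model(dos_v, irr_v, area_v, fe_v, year_shock, y):
        base = (
            cfg.base_yield
            + cfg.effect_dos * dos_v
            + cfg.effect_irrigation * irr_v
            + cfg.effect_temp * t_dev[y]
            + cfg.effect_rain * r_dev[y]
            + cfg.effect_area * area_v
            + fe_v
            + year_shock
        )
        return np.clip(base, 0.0, None)

    shocks = rng.normal(0.0, cfg.noise_sd_yield, (cfg.n_years, cfg.n_fields))
    true_yield = np.stack(
        [
            yield_model(dos, irrig, area_ha, field_effect, shocks[y], y)
            for y in years
        ]
    )  # (n_years, n_fields)
    cut_noise = rng.normal(0.0, cfg.noise_sd_cropcut, (cfg.n_years, cfg.n_fields))
    crop_cut = true_yield + cut_noise

    # --- cropland mask: field pixels plus background cropland up to crop_fraction
    mask = np.zeros((rows, cols), dtype=bool)
    field_index = np.full((rows, cols), -1, dtype=int)
    for i, (r0, c0, h, w) in enumerate(rects):
        mask[r0 : r0 + h, c0 : c0 + w] = True
        field_index[r0 : r0 + h, c0 : c0 + w] = i
    target_crop = int(round(cfg.crop_fraction * rows * cols))
    bg_needed = max(0, target_crop - int(mask.sum()))
    non_field = np.flatnonzero(~mask.ravel())
    bg_pix = rng.choice(non_field, size=min(bg_needed, non_field.size), replace=False)
    bg_r, bg_c = np.unravel_index(bg_pix, (rows, cols))
    mask[bg_r, bg_c] = True

    # background cropland behaves like unsampled fields drawn from the same world
    n_bg = bg_pix.size
    bg_dos = rng.integers(0, 61, n_bg)
    bg_irr = rng.integers(1, 4, n_bg)
    bg_fe = rng.normal(0.0, cfg.field_effect_sd, n_bg)
    bg_area = np.full(n_bg, area_ha.mean() if area_ha.size else 0.25)
    bg_shocks = rng.normal(0.0, cfg.noise_sd_yield, (cfg.n_years, n_bg))

    pixel_truth = np.full((cfg.n_years, rows, cols), np.nan)
    for y in years:
        grid = np.full((rows, cols), np.nan)
        inside = field_index >= 0
        grid[inside] = true_yield[y][field_index[inside]]
        grid[bg_r, bg_c] = yield_model(bg_dos, bg_irr, bg_area, bg_fe, bg_shocks[y], y)
        pixel_truth[y] = grid

    yp_true = np.array(
        [np.nanpercentile(pixel_truth[y], 95) for y in years]
    )

    fields_df = pd.DataFrame(
        {
            "field_id": field_ids,
            "dos": dos,
            "irrigations": irrig,
            "plot_area_ha": area_ha,
            "nitrogen_cgkg": nitrogen,
            "soc_dgkg": soc,
            "field_effect": field_effect,
        }
    )
    years_df = pd.DataFrame(
        {
            "year": years,
            "avg_temp_c": avg_temp,
            "total_rain_mm": total_rain,
            "yp_true": yp_true,
        }
    )
    fy = pd.DataFrame(
        {
            "field_id": np.tile(field_ids, cfg.n_years),
            "year": np.repeat(years, cfg.n_fields),
            "true_yield": true_yield.ravel(),
            "yield_kgha": crop_cut.ravel(),
        }
    )
    truth = GroundTruth(
        config=cfg,
        fields=fields_df,
        years=years_df,
        field_years=fy,
        pixel_truth=pixel_truth,
        georef=georef,
    )

    fields = []
    px = cfg.pixel_size
    for i, (r0, c0, h, w) in enumerate(rects):
        x0, x1 = c0 * px, (c0 + w) * px
        y1, y0 = georef.origin_y - r0 * px, georef.origin_y - (r0 + h) * px
        poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        fields.append(
            FieldRecord(
                field_id=int(i),
                polygon=poly,
                center=poly.centroid,
                covariates={
                    "dos": int(dos[i]),
                    "irrigations": int(irrig[i]),
                    "plot_area_ha": float(area_ha[i]),
                    "nitrogen_cgkg": float(nitrogen[i]),
                    "soc_dgkg": float(soc[i]),
                },
                crop_cuts={int(y): float(crop_cut[y, i]) for y in years},
            )
        )

    scenes = None
    if render_scenes:
        scenes = {}
        for y in years:
            scenes[int(y)] = [
                _render_scene(d, pixel_truth[y], mask, georef)
                for d in cfg.scene_dates_per_year
            ]
    return scenes, fields, mask, truth


def _render_scene(day, yield_grid, mask, georef) -> SpectralScene:
    """Bands for one date: green flat, NIR encodes the intended GCVI exactly."""
    gcvi = np.where(
        mask, _gcvi_at(float(day), np.nan_to_num(yield_grid)), _NONCROP_GCVI
    )
    green = np.full(gcvi.shape, _GREEN_REFLECTANCE)
    nir = green * (gcvi + 1.0)
    blue = np.full(gcvi.shape, 0.05)
    red = np.full(gcvi.shape, 0.06)
    return SpectralScene(
        date=int(day),
        bands={"blue": blue, "green": green, "red": red, "nir": nir},
        georef=georef,
    )


def driver_table_from_truth(truth: GroundTruth) -> pd.DataFrame:
    """Field-year driver table with the *true* yield gap as response.

    The gap is the year's true 95th-percentile cropland pixel yield minus
    the field's true yield — the ground-truth counterpart of the table the
    driver analysis builds from satellite estimates. Used to test driver
    attribution and scenario recovery without confounding them with
    yield-model error.
    """
    out = truth.table().merge(truth.years[["year", "yp_true"]], on="year")
    out["yg"] = out["yp_true"] - out["true_yield"]
    return out


def truth_ideal_gains(
    truth: GroundTruth, ideal_dos: int | None, ideal_irrig: int | None
) -> np.ndarray:
    """Analytic per-field yield gain (kg/ha) from moving to ideal management.

    ``None`` leaves that management variable untouched. Linearity of the
    generating model makes the gain exact and year-independent.
    """
    cfg = truth.config
    gain = np.zeros(len(truth.fields))
    if ideal_dos is not None:
        gain += cfg.effect_dos * (ideal_dos - truth.fields["dos"].to_numpy())
    if ideal_irrig is not None:
        gain += cfg.effect_irrigation * (
            ideal_irrig - truth.fields["irrigations"].to_numpy()
        )
    return gain


def truth_closure_fraction(
    truth: GroundTruth, ideal_dos: int | None, ideal_irrig: int | None
) -> float:
    """Known mean yield gain under ideal management over the mean true yield gap.

    The true yield gap of a field-year is the year's 95th-percentile
    cropland pixel yield minus the field's true yield. This is the recovery
    target for the scenario simulation.
    """
    gains = truth_ideal_gains(truth, ideal_dos, ideal_irrig)
    fy = truth.field_years.merge(truth.years[["year", "yp_true"]], on="year")
    true_gap = fy["yp_true"] - fy["true_yield"]
    mean_gap = float(true_gap.mean())
    if mean_gap == 0:
        return 0.0
    return float(gains.mean() / mean_gap)
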