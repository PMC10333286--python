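"""Empirical yield potential and per-field yield gaps.

Yield potential Yp for a year is defined empirically as the 95th
percentile of the year's cropland pixel-yield distribution — an
economically achievable ceiling already subject to the region's real
infrastructural and management constraints, rather than a crop-model
potential. The yield gap of a field is then

    YG = Yp - Ymean,

where Ymean is the field's mean satellite-estimated pixel yield. Gaps can
be negative for fields above the 95th percentile and are deliberately not
clamped: clamping would bias mean gaps upward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .yield_model import YieldRaster

__all__ = [
    "yield_potential",
    "compute_yield_gaps",
    "summarize_gaps",
    "gap_as_percent_of_mean",
]


def yield_potential(raster: YieldRaster, percentile: float = 95.0) -> float:
    """Percentile of masked pixel yields (linear interpolation), kg/ha."""
    vals = raster.masked_values()
    if vals.size == 0:
        raise ValueError("cropland mask selects no finite pixels; Yp undefined")
    return float(np.percentile(vals, percentile))


def compute_yield_gaps(ymean, yp: float, year: int, field_ids=None) -> pd.DataFrame:
    """Per-field yield-gap rows (field_id, year, ymean, yp, yg) for one year."""
    ymean = np.asarray(ymean, dtype=float)
    if not np.isfinite(yp):
        raise ValueError("yield potential must be finite")
    if field_ids is None:
        field_ids = np.arange(len(ymean))
    return pd.DataFrame(
        {
            "field_id": np.asarray(field_ids),
            "year": year,
            "ymean": ymean,
            "yp": float(yp),
            "yg": float(yp) - ymean,
        }
    )


def summarize_gaps(table: pd.DataFrame) -> pd.DataFrame:
    """Per-year mean gap with a normal-approximation 95% CI half-width."""
    def _one(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        mean_yg = g["yg"].mean()
        sd = g["yg"].std(ddof=1) if n > 1 else 0.0
        return pd.Series(
            {
                "n_fields": n,
                "mean_yg": mean_yg,
                "ci95_halfwidth": 1.96 * sd / np.sqrt(n) if n > 1 else np.nan,
                "mean_ymean": g["ymean"].mean(),
                "yg_pct_of_mean": 100.0 * mean_yg / g["ymean"].mean(),
            }
        )

    return table.groupby("year").apply(_one, include_groups=False).reset_index()


def gap_as_percent_of_mean(table: pd.DataFrame) -> float:
    """Pooled mean gap as a percent of pooled mean yield over all field-years."""
    mean_ymean = table["ymean"].mean()
    if mean_ymean <= 0:
        raise ValueError("mean yield must be positive")
    return float(100.0 * table["yg"].mean() / mean_ymean)
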