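"""Yield persistence across years: decile analysis and anomaly persistence.

Two complementary views of whether the same fields stay high- or
low-yielding over time. The decile analysis ranks all fields by their
base-year yield into ten groups and then looks at the distribution of
those same groups' yields in every later year: persistent yields keep the
decile boxplots separated, non-persistent yields collapse them together.
The anomaly statistic takes the top base-year decile, computes its mean
yield anomaly from the site mean in the base year (A_base) and the mean
anomaly of the same fields across all later years (A_later), and reports

    persistence = 100 * A_later / A_base   (percent).

100% means high-yield fields keep their full advantage; 0% means yield
rankings reshuffle completely from year to year. Anomalies are absolute
(kg/ha) and taken from each year's own site mean, so additive year effects
(weather, prices of inputs, ...) cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "YieldPanel",
    "assign_deciles",
    "decile_distributions",
    "persistence_percent",
]


@dataclass
class YieldPanel:
    """Field-by-year matrix of satellite-estimated mean yields (kg/ha).

    ``yields`` is a DataFrame indexed by field_id with one column per
    year; every field must be present in every year. ``base_year`` names
    the column used for ranking.
    """

    yields: pd.DataFrame
    base_year: object

    def __post_init__(self) -> None:
        if self.base_year not in self.yields.columns:
            raise ValueError(f"base year {self.base_year!r} not a panel column")
        if self.yields.isna().any().any():
            raise ValueError("panel has missing field-years")
        if self.yields.shape[1] < 2:
            raise ValueError("panel needs at least one year beyond the base year")

    @property
    def later_years(self) -> list:
        return [c for c in self.yields.columns if c != self.base_year]


def assign_deciles(base_yields) -> np.ndarray:
    """Decile label (1 = lowest .. 10 = highest) per field by base-year rank.

    Fields are sorted ascending (stable, so ties keep input order) and cut
    into ten contiguous rank groups whose sizes differ by at most one; the
    larger groups come first, matching ``np.array_split``.
    """
    y = np.asarray(base_yields, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 fields to form deciles, got {n}")
    order = np.argsort(y, kind="stable")
    labels = np.empty(n, dtype=int)
    for d, chunk in enumerate(np.array_split(order, 10), start=1):
        labels[chunk] = d
    return labels


def decile_distributions(panel: YieldPanel, deciles=None) -> pd.DataFrame:
    """Five-number summary per base-year decile, pooled over later years.

    Each field keeps the decile assigned from its base-year yield; the
    summary covers all of that group's yields in all non-base years. The
    ``iqr_overlap_next`` column is the fraction of a decile's IQR covered
    by the next decile's IQR — near zero for strongly persistent panels,
    large when deciles are indistinguishable.
    """
    if deciles is None:
        deciles = assign_deciles(panel.yields[panel.base_year].to_numpy())
    deciles = np.asarray(deciles)
    later = panel.yields[panel.later_years].to_numpy()
    rows = []
    for d in range(1, 11):
        vals = later[deciles == d].ravel()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "decile": d,
                "n": vals.size,
                "min": vals.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": vals.max(),
            }
        )
    out = pd.DataFrame(rows)
    overlap = [np.nan] * 10
    for i in range(9):
        lo = max(out.loc[i, "q1"], out.loc[i + 1, "q1"])
        hi = min(out.loc[i, "q3"], out.loc[i + 1, "q3"])
        width = out.loc[i, "q3"] - out.loc[i, "q1"]
        overlap[i] = max(0.0, hi - lo) / width if width > 0 else float(hi >= lo)
    out["iqr_overlap_next"] = overlap
    return out


def persistence_percent(panel: YieldPanel, deciles=None, relative: bool = False) -> float:
    """Percent of the top decile's base-year yield anomaly that persists.

    A_base: mean over top-decile fields of (yield - site mean) in the base
    year. A_later: mean over the same fields and all later years of
    (yield - that year's site mean), each field-year weighted equally.
    Returns ``100 * A_later / A_base``; rejects panels whose base-year top
    decile has non-positive mean anomaly (degenerate ranking). Anomalies
    are absolute (kg/ha) by default; ``relative=True`` divides each
    anomaly by its year's site mean first.
    """
    base = panel.yields[panel.base_year].to_numpy(dtype=float)
    if deciles is None:
        deciles = assign_deciles(base)
    top = np.asarray(deciles) == 10
    a_base = base[top].mean() - base.mean()
    if relative:
        a_base /= base.mean()
    if a_base <= 0:
        raise ValueError("base-year top-decile anomaly is not positive")
    later = panel.yields[panel.later_years].to_numpy(dtype=float)
    anomalies = later[top] - later.mean(axis=0)  # subtract each year's site mean
    if relative:
        anomalies = anomalies / later.mean(axis=0)
    a_later = anomalies.mean()
    return float(100.0 * a_later / a_base)
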