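"""Scene preprocessing: green chlorophyll vegetation index and histogram matching.

The yield estimation chain works on the green chlorophyll vegetation index

    GCVI = NIR / green - 1,

which is linearly related to wheat leaf area index and therefore tracks
canopy development through the season. Scenes from high-resolution sensors
delivered as top-of-atmosphere reflectance are harmonised to surface
reflectance by empirical-CDF histogram matching against reference scenes
(in the original workflow, Landsat surface reflectance bracketing the
acquisition date).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .georef import GridGeoref

__all__ = [
    "BAND_ORDER",
    "SpectralScene",
    "GCVIStack",
    "compute_gcvi",
    "histogram_match",
    "date_weights_from_gaps",
]

#: Band order used everywhere a scene is stored as a 3-D array.
BAND_ORDER = ("blue", "green", "red", "nir")


@dataclass
class SpectralScene:
    """One dated multi-band surface-reflectance grid.

    ``bands`` maps band name -> 2-D float array; all bands share one shape
    and reflectance is unitless and non-negative.
    """

    date: object  # day-of-season int or datetime.date; only ordering is used
    bands: dict = field(default_factory=dict)
    georef: GridGeoref | None = None

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(b).shape for name, b in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"band grids differ in shape: {shapes}")
        for name, b in self.bands.items():
            arr = np.asarray(b, dtype=float)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"band {name!r} contains negative reflectance")
            self.bands[name] = arr

    @property
    def shape(self):
        return next(iter(self.bands.values())).shape

    def as_array(self) -> np.ndarray:
        """Stack bands into a ``(4, rows, cols)`` array in :data:`BAND_ORDER`."""
        return np.stack([self.bands[name] for name in BAND_ORDER])


@dataclass
class GCVIStack:
    """Ordered multi-date GCVI layers for one growing season."""

    dates: list
    layers: np.ndarray  # (n_dates, rows, cols)
    georef: GridGeoref | None = None

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (n_dates, rows, cols) array")
        if len(self.dates) != self.layers.shape[0]:
            raise ValueError(
                f"{len(self.dates)} dates but {self.layers.shape[0]} layers"
            )
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    @property
    def shape(self):
        return self.layers.shape[1:]

    def pixel_features(self) -> np.ndarray:
        """Per-pixel GCVI feature vectors, shape ``(rows*cols, n_dates)``."""
        return self.layers.reshape(self.layers.shape[0], -1).T


def compute_gcvi(scene: SpectralScene) -> np.ndarray:
    """Green chlorophyll vegetation index, ``NIR / green - 1``, per pixel.

    Pixels where the green band is zero (no reflectance signal, e.g. fill)
    get NaN. Values are >= -1 wherever defined because reflectance is
    non-negative.
    """
    green = scene.bands["green"]
    nir = scene.bands["nir"]
    if green.shape != nir.shape:
        raise ValueError("green and nir band shapes differ")
    out = np.full(green.shape, np.nan)
    ok = green > 0
    out[ok] = nir[ok] / green[ok] - 1.0
    return out


def date_weights_from_gaps(target_date: float, before_date: float, after_date: float):
    """Inverse day-gap weights for blending two bracketing reference scenes.

    The reference closer in time gets the larger weight; weights sum to 1.
    With ``before == after == target`` the split is even.
    """
    gap_b = abs(target_date - before_date)
    gap_a = abs(after_date - target_date)
    total = gap_b + gap_a
    if total == 0:
        return (0.5, 0.5)
    # weight of 'before' is proportional to the *other* gap
    return (gap_a / total, gap_b / total)


def _matched_band(target: np.ndarray, ref_b: np.ndarray, ref_a: np.ndarray, w1, w2):
    """CDF-match one band against the w-weighted quantile blend of two refs."""
    flat = target.ravel()
    valid = np.isfinite(flat)
    out = np.full(flat.shape, np.nan)
    vals = flat[valid]
    if vals.size:
        # plotting positions of target pixels within their own empirical CDF
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(vals.size)
        ranks[order] = np.arange(vals.size)
        p = (ranks + 0.5) / vals.size
        rb = ref_b[np.isfinite(ref_b)].ravel()
        ra = ref_a[np.isfinite(ref_a)].ravel()
        q = w1 * np.quantile(rb, p) + w2 * np.quantile(ra, p)
        # equal target values must stay equal after matching
        uniq, inv = np.unique(vals, return_inverse=True)
        q = np.bincount(inv, weights=q) / np.bincount(inv)
        out[valid] = q[inv]
    return out.reshape(target.shape)


def histogram_match(
    target: SpectralScene,
    ref_before: SpectralScene,
    ref_after: SpectralScene | None = None,
    date_weights: Sequence[float] | None = None,
) -> SpectralScene:
    """Remap each band of ``target`` onto a blended reference distribution.

    Every target pixel is sent to the blended reference quantile function
    ``Q_mix(p) = w1 * Q_before(p) + w2 * Q_after(p)`` evaluated at the
    pixel's own empirical quantile ``p``. Blending quantile functions
    (rather than densities) keeps the remapping monotone, so the rank order
    of target pixels within each band is preserved.

    With ``ref_after=None`` or ``date_weights=(1, 0)`` this is plain
    single-reference histogram matching. When ``date_weights`` is omitted
    and both references are given, inverse day-gap weights are derived from
    the three scene dates.
    """
    if ref_after is None:
        ref_after = ref_before
        date_weights = (1.0, 0.0)
    if date_weights is None:
        date_weights = date_weights_from_gaps(
            target.date, ref_before.date, ref_after.date
        )
    w1, w2 = float(date_weights[0]), float(date_weights[1])
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError(f"date_weights must be non-negative and sum to 1, got {(w1, w2)}")
    missing = set(target.bands) - set(ref_before.bands) & set(ref_after.bands)
    if set(target.bands) - set(ref_before.bands) or set(target.bands) - set(ref_after.bands):
        raise ValueError(f"references lack target bands: {sorted(missing)}")
    matched = {}
    for name, band in target.bands.items():
        rb, ra = ref_before.bands[name], ref_after.bands[name]
        if rb.size == 0 or ra.size == 0 or not (
            np.isfinite(rb).any() and np.isfinite(ra).any()
        ):
            raise ValueError(f"empty reference distribution for band {name!r}")
        matched[name] = _matched_band(band, rb, ra, w1, w2)
    if not matched:
        warnings.warn("histogram_match called on a scene with no bands")
    return SpectralScene(date=target.date, bands=matched, georef=target.georef)
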