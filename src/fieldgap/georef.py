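"""Minimal grid georeferencing for north-up rasters in a projected CRS.

All geometry in this package lives in a projected coordinate system with
metre units. A raster is an ``(rows, cols)`` array whose row 0 is the
northernmost row; :class:`GridGeoref` maps array indices to map
coordinates. This deliberately supports only axis-aligned, square-pixel
grids — rotation/shear terms of a full affine transform are never needed
for the scenes handled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeoref"]


@dataclass(frozen=True)
class GridGeoref:
    """Georeference of a north-up raster grid.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates (metres) of the grid's top-left corner.
    pixel_size : float
        Side length of one square pixel, metres.
    crs_id : str
        Identifier of the projected CRS (informational only).
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def pixel_center(self, row, col):
        """Map coordinates of the center(s) of pixel ``(row, col)``."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def center_grids(self, shape):
        """Two ``shape`` arrays with the x and y center coordinate of every pixel."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.pixel_center(rows, cols)

    def to_dict(self) -> dict:
        return {
            "origin_x": float(self.origin_x),
            "origin_y": float(self.origin_y),
            "pixel_size": float(self.pixel_size),
            "crs_id": self.crs_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeoref":
        return cls(
            origin_x=d["origin_x"],
            origin_y=d["origin_y"],
            pixel_size=d["pixel_size"],
            crs_id=d.get("crs_id", "local-metric"),
        )
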