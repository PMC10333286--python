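"""Raster and manifest I/O.

Rasters travel as plain multi-band TIFF written by ``tifffile`` with a
small YAML sidecar (``<name>.tif.yml``) carrying the georeference, band
names and any scalar metadata — functionally a GeoTIFF split into image +
tags, readable anywhere without GDAL.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .georef import GridGeoref
from .preprocess import BAND_ORDER, SpectralScene

__all__ = [
    "write_raster",
    "read_raster",
    "write_scene",
    "read_scene",
    "write_manifest",
    "read_manifest",
]


def _sidecar(path) -> Path:
    return Path(str(path) + ".yml")


def write_raster(path, array, georef: GridGeoref | None = None, band_names=None, **meta) -> None:
    """Write a 2-D or (bands, rows, cols) array as TIFF + YAML sidecar."""
    array = np.asarray(array)
    kwargs = {}
    if array.ndim == 3:  # band-sequential planes, not RGB
        kwargs = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(path, array.astype(np.float32), **kwargs)
    side = {"band_names": list(band_names) if band_names else None, **meta}
    if georef is not None:
        side["georef"] = georef.to_dict()
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=True)


def read_raster(path):
    """Read back (array, georef or None, metadata dict)."""
    array = np.asarray(tifffile.imread(path), dtype=float)
    meta = {}
    georef = None
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = yaml.safe_load(fh) or {}
        if "georef" in meta:
            georef = GridGeoref.from_dict(meta.pop("georef"))
    return array, georef, meta


def write_scene(path, scene: SpectralScene) -> None:
    """Persist a scene as a 4-band TIFF in blue/green/red/NIR order."""
    write_raster(
        path, scene.as_array(), scene.georef, band_names=list(BAND_ORDER), date=scene.date
    )


def read_scene(path) -> SpectralScene:
    array, georef, meta = read_raster(path)
    names = meta.get("band_names") or list(BAND_ORDER)
    bands = {name: array[i] for i, name in enumerate(names)}
    return SpectralScene(date=meta.get("date"), bands=bands, georef=georef)


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
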