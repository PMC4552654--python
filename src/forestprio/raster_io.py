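"""Minimal georeferenced raster and GeoJSON I/O.

Rasters are written as single-band TIFFs carrying the GeoTIFF pixel-scale,
tiepoint and nodata tags, with the grid registered at origin (0, 0), row 0 =
north, in an unspecified local metric CRS.  Continuous layers are stored as
float32, categorical layers as uint8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping

# TIFF tag codes used by GeoTIFF
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

FLOAT_NODATA = -9999.0
INT_NODATA = 255


def write_raster(path, array, cell_size, nodata=None, categorical=False):
    """Write a single-band raster with pixel size ``cell_size`` (metres)."""
    path = Path(path)
    arr = np.asarray(array)
    if categorical:
        nodata = INT_NODATA if nodata is None else nodata
        data = arr.astype(np.uint8)
    else:
        nodata = FLOAT_NODATA if nodata is None else nodata
        data = arr.astype(np.float32)
        data = np.where(np.isnan(data), np.float32(nodata), data)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path):
    """Read a raster written by :func:`write_raster`.

    Returns ``(array, cell_size, nodata)``; nodata pixels in float rasters come
    back as NaN.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell_size = 1.0
        nodata = None
        if _TAG_MODEL_PIXEL_SCALE in page.tags:
            cell_size = float(page.tags[_TAG_MODEL_PIXEL_SCALE].value[0])
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    if np.issubdtype(data.dtype, np.floating) and nodata is not None:
        data = data.astype(np.float64)
        data[data == nodata] = np.nan
    return data, cell_size, nodata


def write_geojson(path, geometries, properties=None):
    """Write shapely geometries (+ optional per-feature property dicts)."""
    properties = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties)
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_geojson(path):
    from shapely.geometry import shape

    payload = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in payload["features"]]
    props = [f.get("properties", {}) for f in payload["features"]]
    return geoms, props
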