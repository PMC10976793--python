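"""Raster file I/O: GeoTIFF (via tifffile) and ESRI ASCII grids.

GeoTIFF support is deliberately minimal: single- or multi-band float
rasters in a projected, metre-unit coordinate system, georeferenced by the
ModelPixelScale + ModelTiepoint tag pair.  Geographic (degree) rasters are
rejected rather than silently mis-scaled, since every distance in the
terrain analytics (Sx rays, complexity windows, blur kernels) is in metres.

The ESRI ASCII grid (.asc) is supported as a plain-text alternative; it
carries no CRS, so coordinates are taken to be metres by documented
convention.
"""
from __future__ import annotations

import json
import math
import os

import numpy as np
import tifffile

from .errors import RasterFormatError, UnitsError
from .terrain import ElevationGrid

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_ascii_grid",
    "read_ascii_grid",
    "load_dem",
    "save_dem",
]

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids / values
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_PROJ_LINEAR_UNITS = 3076
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
_LINEAR_METRE = 9001


def _geokey_directory() -> tuple:
    # header (version, revision, minor, nkeys) then (key, location, count, value)
    return (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED,
        _GT_RASTER_TYPE, 0, 1, 1,              # PixelIsArea
        _PROJ_LINEAR_UNITS, 0, 1, _LINEAR_METRE,
    )


def write_geotiff(
    path,
    data: np.ndarray,
    dx: float,
    origin: tuple[float, float],
    band_names: list[str] | None = None,
    nodata: float = -9999.0,
    dtype=np.float32,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a GeoTIFF.

    ``origin`` is the map position of the NW corner of the NW cell.  Band
    names, if given, are stored in the image description as JSON.
    """
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise RasterFormatError(f"expected 2-D or 3-D array, got shape {data.shape}")
    desc = json.dumps({"band_names": band_names}) if band_names else None
    keydir = _geokey_directory()
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(dx), float(dx), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(keydir), keydir),
        (_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        str(path),
        data.astype(dtype),
        photometric="minisblack",
        description=desc or "",
        extratags=extratags,
        metadata=None,
    )


def _tag_value(page, code):
    tag = page.tags.get(code)
    return None if tag is None else tag.value


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible).

    Returns ``(data, dx, origin, nodata, band_names, geokeys)`` where data is
    (bands, rows, cols) float64 and geokeys is a dict of GeoKey id -> value.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = tf.asarray().astype(float)
        if data.ndim == 2:
            data = data[None, :, :]
        scale = _tag_value(page, _MODEL_PIXEL_SCALE)
        tiepoint = _tag_value(page, _MODEL_TIEPOINT)
        keydir = _tag_value(page, _GEO_KEY_DIRECTORY)
        nodata_raw = _tag_value(page, _GDAL_NODATA)
        desc = _tag_value(page, 270)
    if scale is None or tiepoint is None:
        raise RasterFormatError(f"{path}: missing geotransform tags (not a GeoTIFF?)")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise RasterFormatError(f"{path}: non-square cells ({sx} x {sy} m) are not supported")
    # tiepoint maps raster (0,0) corner to model (X, Y)
    i, j, _, X, Y, _ = (float(v) for v in tuple(tiepoint)[:6])
    origin = (X - j * sx, Y + i * sy)
    geokeys = {}
    if keydir is not None:
        kd = tuple(int(v) for v in keydir)
        nkeys = kd[3]
        for k in range(nkeys):
            key, loc, cnt, val = kd[4 + 4 * k: 8 + 4 * k]
            if loc == 0:
                geokeys[key] = val
    nodata = None
    if nodata_raw is not None:
        try:
            nodata = float(str(nodata_raw).strip().strip("\x00"))
        except ValueError:
            nodata = None
    band_names = None
    if desc:
        try:
            band_names = json.loads(desc).get("band_names")
        except (json.JSONDecodeError, AttributeError):
            band_names = None
    return data, sx, origin, nodata, band_names, geokeys


def write_ascii_grid(path, grid: ElevationGrid, nodata: float = -9999.0) -> None:
    """Write an ElevationGrid as an ESRI ASCII grid (full float precision)."""
    x0, y0 = grid.origin
    yll = y0 - grid.nrows * grid.dx
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.dx!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, grid.z, fmt="%.17g")


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (z, dx, origin, nodata)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        z = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterFormatError(f"{path}: missing ASCII grid header field {req!r}")
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if z.shape != (nr, nc):
        raise RasterFormatError(f"{path}: data shape {z.shape} != header ({nr}, {nc})")
    dx = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nr * dx)
    return z, dx, origin, header.get("nodata_value", -9999.0)


def _fill_nodata_nearest(z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return z[tuple(idx)]


def load_dem(path, fill_nodata: bool = False) -> ElevationGrid:
    """Load a DEM from a GeoTIFF or ESRI ASCII grid.

    Preconditions: single band, square cells, projected metre-unit CRS (for
    GeoTIFF, checked via GeoKeys; ASCII grids are metres by convention).
    Nodata cells are rejected with a count, or filled from the nearest valid
    cell when ``fill_nodata`` is set.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".asc":
        z, dx, origin, nodata = read_ascii_grid(path)
    else:
        data, dx, origin, nodata, _names, geokeys = read_geotiff(path)
        model_type = geokeys.get(_GT_MODEL_TYPE)
        if model_type == _MODEL_TYPE_GEOGRAPHIC:
            raise UnitsError(
                f"{path}: raster is in a geographic (degree) CRS; reproject to a "
                "projected metre-unit system first"
            )
        units = geokeys.get(_PROJ_LINEAR_UNITS)
        if units is not None and units != _LINEAR_METRE:
            raise UnitsError(f"{path}: linear units geokey {units} is not metres")
        if data.shape[0] != 1:
            raise RasterFormatError(f"{path}: expected a single-band DEM, got {data.shape[0]} bands")
        z = data[0]
    bad = ~np.isfinite(z)
    if nodata is not None:
        bad |= z == nodata
    if bad.any():
        if not fill_nodata:
            raise RasterFormatError(
                f"{path}: {int(bad.sum())} nodata/non-finite cells; pass fill_nodata=True to "
                "fill them from the nearest valid cell"
            )
        z = _fill_nodata_nearest(z, bad)
    return ElevationGrid(z=z, dx=dx, origin=origin)


def save_dem(path, grid: ElevationGrid, nodata: float = -9999.0) -> None:
    """Save a DEM.  GeoTIFFs keep float64 so write->read round-trips are
    bit-exact; use :func:`write_geotiff` directly for float32 products."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".asc":
        write_ascii_grid(path, grid, nodata=nodata)
    else:
        write_geotiff(path, grid.z, grid.dx, grid.origin, nodata=nodata, dtype=np.float64)
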