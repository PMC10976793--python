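"""Elevation grids, synthetic terrain, and terrain-derived scalar fields.

This module holds the raster data model (:class:`ElevationGrid`) plus every
terrain-only quantity that feeds the updraft models: slope and aspect,
Gaussian smoothing of the elevation field, the Winstral-style exposure /
sheltering angle ``Sx`` evaluated downwind, and a windowed terrain-complexity
index ``tc``.

Conventions
-----------
* Grids are "north-up": row 0 is the northern edge and rows increase
  southward.  Cell size ``dx`` is uniform in both axes and in metres.
* Azimuths are compass degrees: 0 = north, 90 = east, clockwise.
* Aspect is the azimuth the *downslope* face points toward, so a slope whose
  aspect equals the meteorological wind direction faces directly into the
  wind.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import GridError, InvalidParameterError

__all__ = [
    "ElevationGrid",
    "TerrainMetrics",
    "SxConfig",
    "generate_gaussian_ridge",
    "generate_plane",
    "generate_flat",
    "compute_slope_aspect",
    "blur_sigma",
    "gaussian_blur",
    "blur_elevation",
    "sx_single_azimuth",
    "sx_field",
    "terrain_complexity",
]

#: Relief below this (metres) is treated as flat when normalising tc.
_RELIEF_EPS = 1e-6

#: Ray samples within this many cells of the domain edge count as inside.
#: Without it, trigonometric rounding (e.g. cos 60 vs sin 150) makes
#: boundary-grazing samples flicker in and out under grid rotations.
EDGE_TOL = 1e-9


@dataclasses.dataclass(frozen=True, eq=False)
class ElevationGrid:
    """A uniformly spaced, north-up elevation raster.

    Parameters
    ----------
    z
        2-D elevation array in metres, shape (nrows, ncols), row 0 north.
    dx
        Cell size in metres, identical in both axes.
    origin
        Map coordinates (x, y) of the **north-west corner** of the
        north-west cell (the GDAL geotransform convention).  Cell centres
        then sit at ``x = x0 + (col + 0.5) dx`` and ``y = y0 - (row + 0.5) dx``.
    """

    z: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
            raise GridError(f"elevation array must be 2-D with >= 2 rows/cols, got shape {z.shape}")
        if not np.all(np.isfinite(z)):
            raise GridError("elevation array contains non-finite values")
        if not (self.dx > 0):
            raise InvalidParameterError(f"cell size dx must be positive, got {self.dx}")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "dx", float(self.dx))
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.z.shape[0]

    @property
    def ncols(self) -> int:
        return self.z.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def cell_center(self, row, col):
        """Map coordinates (x, y) of a cell centre.  Accepts arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.dx
        y = y0 - (np.asarray(row) + 0.5) * self.dx
        return x, y

    def fractional_index(self, x, y):
        """Fractional (row, col) of a map position; inverse of cell_center."""
        x0, y0 = self.origin
        col = (np.asarray(x) - x0) / self.dx - 0.5
        row = (y0 - np.asarray(y)) / self.dx - 0.5
        return row, col

    def contains(self, x, y) -> np.ndarray | bool:
        """True where (x, y) lies inside the cell-centre hull (the region on
        which bilinear interpolation of cell-centre values is defined)."""
        row, col = self.fractional_index(x, y)
        return (row >= 0) & (row <= self.nrows - 1) & (col >= 0) & (col <= self.ncols - 1)

    def with_z(self, z: np.ndarray) -> "ElevationGrid":
        """A copy of this grid carrying a different elevation array."""
        return ElevationGrid(z=z, dx=self.dx, origin=self.origin)

    # equality helper used by tests / round-trips
    def equals(self, other: "ElevationGrid") -> bool:
        return (
            self.shape == other.shape
            and self.dx == other.dx
            and self.origin == other.origin
            and bool(np.array_equal(self.z, other.z))
        )


@dataclasses.dataclass(frozen=True, eq=False)
class TerrainMetrics:
    """Per-cell slope angle and aspect azimuth.

    ``slope`` is in radians in [0, pi/2); ``aspect`` in degrees in [0, 360),
    the azimuth the downslope face points toward (0 = north, clockwise).
    Perfectly flat cells carry slope 0 and aspect 0 by convention.
    ``source_blur_sigma`` records the Gaussian smoothing (metres) applied to
    the elevation field before differentiation; 0 means unblurred.
    """

    slope: np.ndarray
    aspect: np.ndarray
    source_blur_sigma: float = 0.0


@dataclasses.dataclass(frozen=True)
class SxConfig:
    """Search-fan geometry for the exposure/sheltering parameter Sx.

    Defaults follow the standard usage: a 30-degree fan (half-width 15)
    sampled every 5 degrees (7 rays) out to dmax = 500 m.
    """

    window_halfwidth: float = 15.0
    increment: float = 5.0
    dmax: float = 500.0

    def __post_init__(self) -> None:
        if not (self.window_halfwidth > 0):
            raise InvalidParameterError("window_halfwidth must be positive")
        if not (self.increment > 0):
            raise InvalidParameterError("increment must be positive")
        n = 2.0 * self.window_halfwidth / self.increment
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "increment must divide the full window evenly "
                f"(2*{self.window_halfwidth}/{self.increment} is not integral)"
            )
        if not (self.dmax > 0):
            raise InvalidParameterError("dmax must be positive")

    @property
    def offsets(self) -> np.ndarray:
        """Angular offsets of the search rays relative to the fan centre."""
        n = int(round(2.0 * self.window_halfwidth / self.increment)) + 1
        return self.window_halfwidth * np.linspace(-1.0, 1.0, n)


# ---------------------------------------------------------------------------
# synthetic terrain generators
# ---------------------------------------------------------------------------

def _center_coords(shape, dx, origin):
    nr, nc = shape
    x0, y0 = origin
    x = x0 + (np.arange(nc) + 0.5) * dx
    y = y0 - (np.arange(nr) + 0.5) * dx
    return np.meshgrid(x, y)  # (X, Y), each (nr, nc)


def generate_gaussian_ridge(
    shape: tuple[int, int],
    dx: float,
    peak_height: float,
    width_sigma: float,
    ridge_azimuth: float = 0.0,
    base_elevation: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ElevationGrid:
    """An infinite Gaussian ridge through the domain centre.

    The elevation is ``base + peak_height * exp(-d^2 / (2 width_sigma^2))``
    where ``d`` is the perpendicular map distance to the ridge line, which
    runs through the domain centre at azimuth ``ridge_azimuth``.  With
    ``ridge_azimuth = 0`` the ridge runs north--south.
    """
    if not (width_sigma > 0):
        raise InvalidParameterError("width_sigma must be positive")
    if not (dx > 0):
        raise InvalidParameterError("dx must be positive")
    if peak_height < 0:
        raise InvalidParameterError("peak_height must be non-negative")
    X, Y = _center_coords(shape, dx, origin)
    x0, y0 = origin
    cx = x0 + shape[1] * dx / 2.0
    cy = y0 - shape[0] * dx / 2.0
    az = math.radians(ridge_azimuth)
    # unit normal to the ridge direction (ridge direction = (sin az, cos az))
    nx, ny = math.cos(az), -math.sin(az)
    d = (X - cx) * nx + (Y - cy) * ny
    z = base_elevation + peak_height * np.exp(-(d ** 2) / (2.0 * width_sigma ** 2))
    return ElevationGrid(z=z, dx=dx, origin=origin)


def generate_plane(
    shape: tuple[int, int],
    dx: float,
    gradient_magnitude: float,
    gradient_azimuth: float = 0.0,
    base_elevation: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ElevationGrid:
    """A uniformly sloping plane; elevation increases toward gradient_azimuth.

    ``gradient_magnitude`` is rise/run (dimensionless).  The plane passes
    through ``base_elevation`` at the domain centre.
    """
    if gradient_magnitude < 0:
        raise InvalidParameterError("gradient_magnitude must be non-negative")
    X, Y = _center_coords(shape, dx, origin)
    x0, y0 = origin
    cx = x0 + shape[1] * dx / 2.0
    cy = y0 - shape[0] * dx / 2.0
    az = math.radians(gradient_azimuth)
    z = base_elevation + gradient_magnitude * ((X - cx) * math.sin(az) + (Y - cy) * math.cos(az))
    return ElevationGrid(z=z, dx=dx, origin=origin)


def generate_flat(
    shape: tuple[int, int],
    dx: float,
    elevation: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ElevationGrid:
    """A constant-elevation grid."""
    return ElevationGrid(z=np.full(shape, float(elevation)), dx=dx, origin=origin)


# ---------------------------------------------------------------------------
# slope / aspect
# ---------------------------------------------------------------------------

def compute_slope_aspect(grid: ElevationGrid, source_blur_sigma: float = 0.0) -> TerrainMetrics:
    """Per-cell slope angle and downslope aspect.

    Interior cells use the Horn 3x3 weighted finite-difference stencil;
    border cells fall back to one-sided differences.  Slope is
    ``arctan |grad z|``; aspect is the azimuth of ``-grad z`` (the direction
    the slope face points toward), degrees clockwise from north.  Exactly
    flat cells get slope 0 and aspect 0.
    """
    z, dx = grid.z, grid.dx
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise GridError("grid smaller than the difference stencil")

    # Horn weights; correlate keeps the written orientation (no kernel flip).
    kx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 8.0
    ky = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]]) / 8.0
    gx = ndimage.correlate(z, kx, mode="nearest") / dx       # d z / d east
    gy = ndimage.correlate(z, ky, mode="nearest") / dx       # d z / d north

    # one-sided differences on the border ring
    gcol = np.gradient(z, dx, axis=1)
    grow = np.gradient(z, dx, axis=0)
    border = np.zeros(z.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    gx = np.where(border, gcol, gx)
    gy = np.where(border, -grow, gy)

    mag = np.hypot(gx, gy)
    slope = np.arctan(mag)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(mag == 0.0, 0.0, aspect)
    return TerrainMetrics(slope=slope, aspect=aspect, source_blur_sigma=float(source_blur_sigma))


# ---------------------------------------------------------------------------
# Gaussian smoothing of the elevation field
# ---------------------------------------------------------------------------

def blur_sigma(h: float) -> float:
    """Smoothing scale (metres) as a function of height AGL.

    sigma = min(0.8 h + 16, 300).  The cap keeps the kernel bounded at
    heights far above the terrain-influenced layer.
    """
    if not (h > 0):
        raise InvalidParameterError(f"height AGL must be positive, got {h}")
    return min(0.8 * h + 16.0, 300.0)


def gaussian_blur(grid: ElevationGrid, sigma_m: float) -> ElevationGrid:
    """Isotropic Gaussian smoothing with standard deviation sigma_m metres.

    Reflective boundary handling preserves total elevation mass.  sigma 0
    returns the grid unchanged.
    """
    if sigma_m < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if sigma_m == 0:
        return grid
    zb = ndimage.gaussian_filter(grid.z, sigma=sigma_m / grid.dx, mode="reflect")
    return grid.with_z(zb)


def blur_elevation(grid: ElevationGrid, h: float) -> ElevationGrid:
    """Smooth the elevation field with the height-dependent kernel."""
    return gaussian_blur(grid, blur_sigma(h))


# ---------------------------------------------------------------------------
# bilinear sampling helper (shared by Sx and the movement model)
# ---------------------------------------------------------------------------

def bilinear_sample(z: np.ndarray, row, col):
    """Bilinear interpolation of a cell-centre field at fractional indices.

    Valid for row in [0, nrows-1] and col in [0, ncols-1]; the caller is
    responsible for masking out-of-range points.
    """
    nr, nc = z.shape
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    r0 = np.clip(np.floor(row).astype(int), 0, nr - 2)
    c0 = np.clip(np.floor(col).astype(int), 0, nc - 2)
    fr = row - r0
    fc = col - c0
    z00 = z[r0, c0]
    # incremental form: exact for constant fields and at cell centres
    return (
        z00
        + fr * (z[r0 + 1, c0] - z00)
        + fc * (z[r0, c0 + 1] - z00)
        + fr * fc * (z[r0 + 1, c0 + 1] - z[r0 + 1, c0] - z[r0, c0 + 1] + z00)
    )


# ---------------------------------------------------------------------------
# Winstral-style exposure / sheltering angle
# ---------------------------------------------------------------------------

def sx_single_azimuth(
    grid: ElevationGrid,
    cell: tuple[int, int],
    azimuth: float,
    dmax: float = 500.0,
) -> float:
    """Maximum elevation angle from one cell to terrain along one ray.

    Samples the elevation (bilinearly interpolated) at distances
    dx, 2 dx, ... <= dmax along ``azimuth`` from the cell centre and returns
    the maximum of ``arctan((z_v - z_i)/distance)``.  The ray is truncated at
    the grid edge; a ray with no valid sample returns 0.
    """
    row, col = cell
    if not (0 <= row < grid.nrows and 0 <= col < grid.ncols):
        raise GridError(f"cell {cell} outside grid of shape {grid.shape}")
    if dmax < grid.dx:
        raise InvalidParameterError("dmax must be at least one cell size")
    z = grid.z
    zi = z[row, col]
    az = math.radians(azimuth)
    drow = -math.cos(az)  # per unit distance, in cells
    dcol = math.sin(az)
    best = -math.inf
    kmax = int(math.floor(dmax / grid.dx + 1e-9))
    for k in range(1, kmax + 1):
        rr = row + drow * k
        cc = col + dcol * k
        if (
            rr < -EDGE_TOL
            or rr > grid.nrows - 1 + EDGE_TOL
            or cc < -EDGE_TOL
            or cc > grid.ncols - 1 + EDGE_TOL
        ):
            break
        zv = float(bilinear_sample(z, min(max(rr, 0.0), grid.nrows - 1), min(max(cc, 0.0), grid.ncols - 1)))
        best = max(best, math.atan((zv - zi) / (k * grid.dx)))
    return best if math.isfinite(best) else 0.0


def sx_field(
    grid: ElevationGrid,
    wdir: float,
    cfg: SxConfig | None = None,
    return_truncation_mask: bool = False,
):
    """Mean maximum *downwind* slope angle (radians) for every cell.

    The search azimuth is flipped relative to the classic upwind definition:
    ``A = (wdir + 180) mod 360`` with ``wdir`` in meteorological "from"
    convention.  The returned field is the arithmetic mean over the fan of
    rays at A + offsets (7 rays for the defaults).  Positive values mark
    windward faces (terrain rising downwind of the cell); negative values
    mark cells above descending downwind terrain.

    With ``return_truncation_mask=True`` also returns a boolean array marking
    cells where at least one ray lost samples to the grid edge.
    """
    cfg = cfg or SxConfig()
    if cfg.dmax < grid.dx:
        raise InvalidParameterError("dmax must be at least one cell size")
    z, dx = grid.z, grid.dx
    nr, nc = z.shape
    A = (wdir + 180.0) % 360.0
    kmax = int(math.floor(cfg.dmax / dx + 1e-9))
    rows = np.arange(nr)[:, None] * np.ones((1, nc))
    cols = np.ones((nr, 1)) * np.arange(nc)[None, :]
    total = np.zeros((nr, nc))
    truncated = np.zeros((nr, nc), dtype=bool)
    for off in cfg.offsets:
        az = math.radians(A + off)
        drow = -math.cos(az)
        dcol = math.sin(az)
        best = np.full((nr, nc), -np.inf)
        for k in range(1, kmax + 1):
            rr = rows + drow * k
            cc = cols + dcol * k
            valid = (
                (rr >= -EDGE_TOL)
                & (rr <= nr - 1 + EDGE_TOL)
                & (cc >= -EDGE_TOL)
                & (cc <= nc - 1 + EDGE_TOL)
            )
            if not valid.any():
                truncated |= True
                break
            zv = bilinear_sample(z, np.clip(rr, 0, nr - 1), np.clip(cc, 0, nc - 1))
            ang = np.arctan((zv - z) / (k * dx))
            best = np.where(valid, np.maximum(best, ang), best)
            truncated |= ~valid
        ray = np.where(np.isfinite(best), best, 0.0)
        total += ray
    sx = total / len(cfg.offsets)
    if return_truncation_mask:
        return sx, truncated
    return sx


# ---------------------------------------------------------------------------
# terrain complexity
# ---------------------------------------------------------------------------

def terrain_complexity(
    grid: ElevationGrid,
    window: float = 500.0,
    return_truncation_mask: bool = False,
):
    """Windowed terrain-complexity index tc in [0, 1].

    For each cell, over the square window of side ``window`` metres centred
    on it (truncated at grid edges):

        tc = (mean(z) - min(z)) / (max(z) - min(z))

    i.e. where the local mean elevation sits between the local extremes.
    Flat-bottomed regions with isolated peaks score low; plateau-and-ravine
    regions score high.  Windows with relief below 1e-6 m get tc = 0.
    """
    if window < grid.dx:
        raise InvalidParameterError("window must be at least one cell size")
    z, dx = grid.z, grid.dx
    nr, nc = z.shape
    hw = int(round(window / (2.0 * dx)))
    size = 2 * hw + 1

    if hw == 0:
        tc = np.zeros((nr, nc))
        if return_truncation_mask:
            return tc, np.zeros((nr, nc), dtype=bool)
        return tc

    # windowed mean via a summed-area table with exact truncated counts
    S = np.zeros((nr + 1, nc + 1))
    S[1:, 1:] = z.cumsum(axis=0).cumsum(axis=1)
    r = np.arange(nr)
    c = np.arange(nc)
    r0 = np.clip(r - hw, 0, nr - 1)
    r1 = np.clip(r + hw, 0, nr - 1)
    c0 = np.clip(c - hw, 0, nc - 1)
    c1 = np.clip(c + hw, 0, nc - 1)
    wsum = (
        S[np.ix_(r1 + 1, c1 + 1)]
        - S[np.ix_(r0, c1 + 1)]
        - S[np.ix_(r1 + 1, c0)]
        + S[np.ix_(r0, c0)]
    )
    count = (r1 - r0 + 1)[:, None] * (c1 - c0 + 1)[None, :]
    wmean = wsum / count

    # 'nearest' padding replicates in-window edge cells, so the filtered
    # extrema equal the truncated-window extrema
    zmin = ndimage.minimum_filter(z, size=size, mode="nearest")
    zmax = ndimage.maximum_filter(z, size=size, mode="nearest")
    relief = zmax - zmin
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(relief < _RELIEF_EPS, 0.0, (wmean - zmin) / np.where(relief == 0, 1.0, relief))
    tc = np.clip(tc, 0.0, 1.0)
    if return_truncation_mask:
        truncated = ((r - hw < 0) | (r + hw > nr - 1))[:, None] | ((c - hw < 0) | (c + hw > nc - 1))[None, :]
        return tc, truncated
    return tc
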