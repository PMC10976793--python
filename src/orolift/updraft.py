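"""Orographic updraft models: the BO04 baseline and the EVVE correction.

The baseline (widely used in movement ecology, here tagged ``bo04``) is the
nondimensional coefficient

    W0 = sin(theta) * cos(alpha - beta)

with slope angle theta, meteorological wind direction alpha and downslope
aspect beta, dimensionalised by a horizontal wind speed.  It is
height-independent and reacts to every local wiggle of the DEM.

The corrected model (tagged ``evve``) evaluates the same coefficient on a
Gaussian-smoothed elevation field (kernel width growing with height AGL),
then rescales it by three empirical factors:

* ``f_h``   height adjustment fitted on simulated flow over Gaussian hills,
* ``f_Sx``  exposure/sheltering from the downwind-looking Sx angle,
* ``f_tc``  terrain-complexity boost growing linearly with height,

composed as ``F = f_Sx * f_tc / f_h`` and dimensionalised by the horizontal
wind speed at the fixed 80 m reference height:

    w = V_ref * F * W0'

The model describes attached, neutrally stratified flow on windward faces;
it does not represent leeward recirculation or buoyant (thermal) updrafts.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import DegenerateFactorError, InvalidParameterError
from .terrain import (
    ElevationGrid,
    SxConfig,
    TerrainMetrics,
    blur_elevation,
    blur_sigma,
    compute_slope_aspect,
    sx_field,
    terrain_complexity,
)

__all__ = [
    "WindScenario",
    "HeightFactorParams",
    "UpdraftField",
    "bo04_coefficient",
    "height_factor",
    "sheltering_factor",
    "complexity_factor",
    "evve_updraft",
    "bo04_updraft",
]

#: Reference height (m AGL) at which the dimensionalising wind speed is taken.
REFERENCE_HEIGHT = 80.0

#: Height (m) normalising the linear growth of the complexity factor.
COMPLEXITY_HEIGHT_SCALE = 40.0

#: Height range (m AGL) over which the height-factor fit is trusted.
TRUSTED_HEIGHT_RANGE = (30.0, 200.0)


@dataclasses.dataclass(frozen=True)
class WindScenario:
    """A wind forcing: direction (met. 'from' convention) and reference speed.

    ``wdir`` in degrees, 0 = wind from the north, clockwise.  ``v_ref`` is
    the horizontal wind speed (m/s) at the 80 m reference height.
    """

    wdir: float
    v_ref: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.wdir < 360.0):
            raise InvalidParameterError(f"wdir must be in [0, 360), got {self.wdir}")
        if self.v_ref < 0:
            raise InvalidParameterError(f"v_ref must be non-negative, got {self.v_ref}")


@dataclasses.dataclass(frozen=True)
class HeightFactorParams:
    """Constants of the height-adjustment surface fit.

    f_h = (a h^2 + b h + c) * d^(-cos(theta) + e) + f
    """

    a: float = 0.00004   # m^-2
    b: float = 0.0028    # m^-1
    c: float = 0.8
    d: float = 0.35
    e: float = 0.095
    f: float = -0.09

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise InvalidParameterError("base d of the exponential term must be positive")


@dataclasses.dataclass(frozen=True, eq=False)
class UpdraftField:
    """A per-cell vertical-velocity field at one height AGL.

    ``w`` is in m/s.  ``components`` retains the intermediate factor fields
    (keys: ``w0`` for the nondimensional coefficient, and for the corrected
    model also ``f_h``, ``f_sx``, ``f_tc``, ``F``).  ``clipped`` marks cells
    zeroed by negative-coefficient clipping, if requested.
    """

    w: np.ndarray
    h: float | None
    components: dict
    scenario: WindScenario
    grid: ElevationGrid
    model_tag: str
    clipped: np.ndarray | None = None


def bo04_coefficient(metrics: TerrainMetrics, wdir: float) -> np.ndarray:
    """Nondimensional updraft coefficient sin(theta) cos(alpha - beta).

    Maximal (= sin theta) where the wind blows squarely onto a slope face,
    zero for winds parallel to slopes and on flat cells; in [-1, 1].
    """
    return np.sin(metrics.slope) * np.cos(np.radians(wdir - metrics.aspect))


def height_factor(
    h: float,
    slope: np.ndarray | float,
    params: HeightFactorParams | None = None,
) -> np.ndarray:
    """Height adjustment f_h evaluated per cell from the (blurred) slope.

    Strictly increasing in height over the trusted 30--200 m range; a
    warning is emitted outside it because the underlying fit was made within
    the rotor-swept zone.
    """
    params = params or HeightFactorParams()
    if not (h > 0):
        raise InvalidParameterError(f"height AGL must be positive, got {h}")
    lo, hi = TRUSTED_HEIGHT_RANGE
    if h < lo or h > hi:
        warnings.warn(
            f"height factor evaluated at h={h} m, outside the fitted range "
            f"[{lo:.0f}, {hi:.0f}] m; treat results with care",
            stacklevel=2,
        )
    slope = np.asarray(slope, dtype=float)
    fh = (params.a * h * h + params.b * h + params.c) * params.d ** (-np.cos(slope) + params.e) + params.f
    if np.any(fh <= 0):
        raise DegenerateFactorError(
            "height factor f_h is non-positive for some cells; it divides the "
            "composed factor and cannot be used"
        )
    return fh


def sheltering_factor(sx: np.ndarray | float) -> np.ndarray:
    """Exposure/sheltering factor f_Sx = 1 + tan(Sx).

    Above 1 on windward faces (positive downwind-looking Sx), below 1 above
    descending downwind terrain.  |Sx| >= 90 deg is rejected rather than
    propagating infinities (it cannot arise from slopes below 45 deg).
    """
    sx = np.asarray(sx, dtype=float)
    if np.any(np.abs(sx) >= np.pi / 2):
        raise InvalidParameterError("|Sx| >= 90 degrees; tangent undefined")
    return 1.0 + np.tan(sx)


def complexity_factor(tc: np.ndarray | float, h: float) -> np.ndarray:
    """Terrain-complexity factor f_tc = 1 + (h / 40 m) * tc; always >= 1."""
    if not (h > 0):
        raise InvalidParameterError(f"height AGL must be positive, got {h}")
    tc = np.asarray(tc, dtype=float)
    if np.any((tc < 0) | (tc > 1)):
        raise InvalidParameterError("tc must lie in [0, 1]")
    return 1.0 + (h / COMPLEXITY_HEIGHT_SCALE) * tc


def evve_updraft(
    grid: ElevationGrid,
    scenario: WindScenario,
    h: float,
    sx_cfg: SxConfig | None = None,
    params: HeightFactorParams | None = None,
    clip_negative: bool = False,
) -> UpdraftField:
    """Corrected three-dimensional updraft field at height ``h`` AGL.

    Pipeline: smooth the DEM with the height-dependent Gaussian kernel,
    differentiate the smoothed surface for slope/aspect, form the baseline
    coefficient W0' on it, then rescale by F = f_Sx * f_tc / f_h where Sx
    and tc are evaluated on the raw DEM (both already integrate over ~500 m
    neighbourhoods) and f_h uses the per-cell blurred slope.  Finally
    w = V_ref * F * W0'.

    With ``clip_negative`` cells where W0' < 0 (leeward, where the model is
    not applicable) are zeroed and flagged in ``clipped``.
    """
    sx_cfg = sx_cfg or SxConfig()
    sigma = blur_sigma(h)
    blurred = blur_elevation(grid, h)
    metrics = compute_slope_aspect(blurred, source_blur_sigma=sigma)
    w0p = bo04_coefficient(metrics, scenario.wdir)
    fh = height_factor(h, metrics.slope, params)
    fsx = sheltering_factor(sx_field(grid, scenario.wdir, sx_cfg))
    ftc = complexity_factor(terrain_complexity(grid), h)
    F = fsx * ftc / fh
    w = scenario.v_ref * F * w0p
    clipped = None
    if clip_negative:
        clipped = w0p < 0
        w = np.where(clipped, 0.0, w)
    components = {"w0": w0p, "f_h": fh, "f_sx": fsx, "f_tc": ftc, "F": F}
    return UpdraftField(
        w=w, h=h, components=components, scenario=scenario, grid=grid,
        model_tag="evve", clipped=clipped,
    )


def bo04_updraft(
    grid: ElevationGrid,
    scenario: WindScenario,
    h: float | None = None,
    clip_negative: bool = False,
) -> UpdraftField:
    """Baseline updraft field w = V_ref sin(theta) cos(alpha - beta).

    Height-independent: ``h`` is carried through only as a label.  Computed
    on the raw, unblurred DEM.
    """
    metrics = compute_slope_aspect(grid)
    w0 = bo04_coefficient(metrics, scenario.wdir)
    w = scenario.v_ref * w0
    clipped = None
    if clip_negative:
        clipped = w0 < 0
        w = np.where(clipped, 0.0, w)
    return UpdraftField(
        w=w, h=h, components={"w0": w0}, scenario=scenario, grid=grid,
        model_tag="bo04", clipped=clipped,
    )
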