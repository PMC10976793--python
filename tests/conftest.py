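import numpy as np
import pytest

from orolift import ElevationGrid, generate_flat
from scipy import ndimage


@pytest.fixture
def flat_grid():
    return generate_flat((40, 40), dx=30.0)


@pytest.fixture
def random_grid():
    """A seeded, smooth-ish random 50x50 terrain used by oracle tests."""
    rng = np.random.default_rng(20240317)
    z = ndimage.gaussian_filter(rng.normal(0.0, 40.0, (50, 50)), 2.0)
    return ElevationGrid(z=z, dx=30.0)


# --- independent brute-force oracles (kept free of orolift internals) ------

def oracle_bilinear(z, r, c):
    """Textbook two-pass bilinear interpolation (rows then columns)."""
    nr, nc = z.shape
    r0 = min(max(int(np.floor(r)), 0), nr - 2)
    c0 = min(max(int(np.floor(c)), 0), nc - 2)
    fr, fc = r - r0, c - c0
    top = z[r0, c0] * (1 - fc) + z[r0, c0 + 1] * fc
    bot = z[r0 + 1, c0] * (1 - fc) + z[r0 + 1, c0 + 1] * fc
    return top * (1 - fr) + bot * fr


def oracle_sx_field(grid, wdir, halfwidth=15.0, increment=5.0, dmax=500.0):
    """Naive per-cell, per-ray, per-sample triple loop for the downwind
    exposure angle."""
    z, dx = grid.z, grid.dx
    nr, nc = z.shape
    A = (wdir + 180.0) % 360.0
    n_off = int(round(2 * halfwidth / increment)) + 1
    offsets = np.linspace(-halfwidth, halfwidth, n_off)
    kmax = int(np.floor(dmax / dx + 1e-9))
    out = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            acc = 0.0
            for off in offsets:
                az = np.radians(A + off)
                drow, dcol = -np.cos(az), np.sin(az)
                best = -np.inf
                tol = 1e-9  # boundary-grazing samples count as inside
                for k in range(1, kmax + 1):
                    rr, cc = r + drow * k, c + dcol * k
                    if rr < -tol or rr > nr - 1 + tol or cc < -tol or cc > nc - 1 + tol:
                        break
                    zv = oracle_bilinear(z, min(max(rr, 0), nr - 1), min(max(cc, 0), nc - 1))
                    best = max(best, np.arctan((zv - z[r, c]) / (k * dx)))
                acc += best if np.isfinite(best) else 0.0
            out[r, c] = acc / n_off
    return out


def oracle_terrain_complexity(grid, window=500.0):
    """Naive windowed relief statistics."""
    z, dx = grid.z, grid.dx
    nr, nc = z.shape
    hw = int(round(window / (2.0 * dx)))
    out = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            win = z[max(r - hw, 0): r + hw + 1, max(c - hw, 0): c + hw + 1]
            relief = win.max() - win.min()
            out[r, c] = 0.0 if relief < 1e-6 else (win.mean() - win.min()) / relief
    return out
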