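"""Heuristic individual-based movement model for orographic soaring birds.

A simulated bird crosses the domain in constant-length steps (default 30 m)
with a fixed intended travel azimuth ``phi``.  At each step it looks one
step ahead along a 60-degree arc (azimuths phi, phi +/- 15, phi +/- 30) and
bilinearly interpolates the updraft field at the five candidate points.  If
the best candidate exceeds the species' soaring threshold ``w_thr``
(0.85 m/s for golden eagles) it moves there; otherwise it picks one of the
five candidates uniformly at random — a directed random walk.  Many tracks
released along a boundary are rasterised and smoothed into a relative
presence-density map.

The walker has no memory and no perception beyond one step: concentration
of presence along updraft corridors is an emergent property of the local
rule, which is exactly what makes the underlying updraft model choice
consequential.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import GridError, InvalidParameterError
from .terrain import bilinear_sample
from .updraft import UpdraftField

__all__ = [
    "IBMMConfig",
    "Track",
    "PresenceMap",
    "sample_updraft",
    "candidate_positions",
    "step_decision",
    "simulate_track",
    "start_positions",
    "presence_map",
]

#: Candidate azimuth offsets (degrees) spanning the 60-degree forward arc.
ARC_OFFSETS = np.array([-30.0, -15.0, 0.0, 15.0, 30.0])

#: Argmax tie preference: closest to phi first, then lowest angular index.
_TIE_ORDER = (2, 1, 3, 0, 4)


@dataclasses.dataclass(frozen=True)
class IBMMConfig:
    """Parameters of the individual-based movement model.

    ``phi`` is the intended travel azimuth (degrees).  ``w_thr`` is the
    threshold updraft (m/s) that sustains soaring; ``step`` the constant
    step length (m); ``n_tracks`` the number of released individuals;
    ``max_steps`` caps track length (default: 3 x domain diagonal / step).
    ``start_edge`` is the release boundary; ``start_jitter`` randomises the
    evenly spaced release points under the master seed.
    """

    phi: float
    w_thr: float = 0.85
    step: float = 30.0
    n_tracks: int = 1000
    max_steps: int | None = None
    seed: int = 0
    start_edge: str = "north"
    start_jitter: bool = False
    smoothing_sigma: float = 2.0  # presence-map kernel, in cells

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise InvalidParameterError("step length must be positive")
        if self.w_thr < 0:
            raise InvalidParameterError("w_thr must be non-negative")
        if self.n_tracks < 1:
            raise InvalidParameterError("n_tracks must be at least 1")
        if self.start_edge not in ("north", "south", "east", "west"):
            raise InvalidParameterError(f"unknown start edge {self.start_edge!r}")


@dataclasses.dataclass(frozen=True, eq=False)
class Track:
    """One simulated flight: ordered map positions and per-step labels.

    ``positions`` has shape (n_steps + 1, 2) in map metres; consecutive
    points are exactly one step length apart.  ``step_kinds`` labels each
    step ``"updraft"`` (moved to the best above-threshold candidate) or
    ``"random"``.  ``terminated_by`` is ``"boundary-exit"`` or ``"max-steps"``;
    only the final point may lie outside the domain.
    """

    positions: np.ndarray
    step_kinds: tuple
    terminated_by: str

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


@dataclasses.dataclass(frozen=True, eq=False)
class PresenceMap:
    """Smoothed relative density of simulated positions over the grid.

    ``density`` is scaled to [0, 1]; ``counts`` is the raw per-cell position
    count before smoothing (its sum equals ``total_positions``).
    """

    density: np.ndarray
    counts: np.ndarray
    n_tracks: int
    smoothing_sigma: float
    total_positions: int


def sample_updraft(field: UpdraftField, position) -> float:
    """Bilinearly interpolated vertical velocity at a map position.

    Returns NaN for positions outside the cell-centre hull (the
    out-of-domain signal used for track termination).  Cell-centre
    positions reproduce the cell values exactly.
    """
    x, y = position
    grid = field.grid
    row, col = grid.fractional_index(x, y)
    if not (0 <= row <= grid.nrows - 1 and 0 <= col <= grid.ncols - 1):
        return math.nan
    return float(bilinear_sample(field.w, row, col))


def candidate_positions(position, phi: float, step: float) -> np.ndarray:
    """The five forward candidates, one step ahead along the 60-degree arc.

    Returns an array of shape (5, 2) ordered by azimuth offset
    (-30, -15, 0, +15, +30 degrees relative to phi).
    """
    az = np.radians(phi + ARC_OFFSETS)
    x, y = position
    return np.column_stack((x + step * np.sin(az), y + step * np.cos(az)))


def _sample_many(field: UpdraftField, pts: np.ndarray) -> np.ndarray:
    """Vectorised sample_updraft over an (n, 2) array; NaN out of domain."""
    grid = field.grid
    row, col = grid.fractional_index(pts[:, 0], pts[:, 1])
    inside = (row >= 0) & (row <= grid.nrows - 1) & (col >= 0) & (col <= grid.ncols - 1)
    out = np.full(len(pts), np.nan)
    if inside.any():
        out[inside] = bilinear_sample(field.w, row[inside], col[inside])
    return out


def step_decision(field: UpdraftField, position, cfg: IBMMConfig, rng: np.random.Generator):
    """One movement decision: the next position and its step kind.

    If the best in-domain candidate updraft strictly exceeds ``cfg.w_thr``
    the bird moves there (ties broken toward phi, then lowest angular
    index); otherwise one of the five candidates is drawn uniformly.  A
    drawn out-of-domain candidate terminates the track at that exit point.
    When *every* candidate is out of domain the bird exits deterministically
    along phi (step kind ``"exit"``).
    """
    cands = candidate_positions(position, cfg.phi, cfg.step)
    w = _sample_many(field, cands)
    finite = np.isfinite(w)
    if not finite.any():
        return cands[2], "exit"
    wmax = np.nanmax(w)
    if wmax > cfg.w_thr:
        for i in _TIE_ORDER:
            if finite[i] and w[i] == wmax:
                return cands[i], "updraft"
    i = int(rng.integers(len(cands)))
    return cands[i], "random"


def _default_max_steps(field: UpdraftField, step: float) -> int:
    grid = field.grid
    diag = math.hypot(grid.nrows * grid.dx, grid.ncols * grid.dx)
    return max(1, int(math.ceil(3.0 * diag / step)))


def simulate_track(
    field: UpdraftField,
    start,
    cfg: IBMMConfig,
    rng: np.random.Generator,
) -> Track:
    """Simulate one bird from ``start`` until it exits the domain or the
    step cap is reached.  Fully reproducible given the generator state."""
    grid = field.grid
    if not bool(grid.contains(start[0], start[1])):
        raise GridError(f"start position {tuple(start)} outside the domain")
    max_steps = cfg.max_steps if cfg.max_steps is not None else _default_max_steps(field, cfg.step)
    positions = [np.asarray(start, dtype=float)]
    kinds = []
    terminated_by = "max-steps"
    for _ in range(max_steps):
        nxt, kind = step_decision(field, positions[-1], cfg, rng)
        positions.append(np.asarray(nxt, dtype=float))
        kinds.append(kind)
        if not bool(grid.contains(nxt[0], nxt[1])):
            terminated_by = "boundary-exit"
            break
    return Track(
        positions=np.vstack(positions),
        step_kinds=tuple(kinds),
        terminated_by=terminated_by,
    )


def start_positions(field: UpdraftField, cfg: IBMMConfig) -> np.ndarray:
    """Release points along the configured boundary edge.

    Evenly spaced by default (one per track, half-spacing inset from the
    corners); with ``start_jitter`` each point is displaced uniformly along
    the edge within its spacing slot, using seeds derived from the master
    seed so starts are independent of the walk randomness.
    """
    grid = field.grid
    n = cfg.n_tracks
    x0, y0 = grid.origin
    # cell-centre hull extents
    xlo = x0 + 0.5 * grid.dx
    xhi = x0 + (grid.ncols - 0.5) * grid.dx
    ylo = y0 - (grid.nrows - 0.5) * grid.dx
    yhi = y0 - 0.5 * grid.dx
    frac = (np.arange(n) + 0.5) / n
    if cfg.start_jitter:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
        frac = (np.arange(n) + rng.random(n)) / n
    if cfg.start_edge in ("north", "south"):
        xs = xlo + frac * (xhi - xlo)
        ys = np.full(n, yhi if cfg.start_edge == "north" else ylo)
    else:
        ys = ylo + frac * (yhi - ylo)
        xs = np.full(n, xhi if cfg.start_edge == "east" else xlo)
    return np.column_stack((xs, ys))


def _track_rng(seed: int, index: int) -> np.random.Generator:
    # counter-style derivation: track i's stream depends only on (seed, i),
    # so growing n_tracks never reshuffles earlier tracks
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, index)))


def simulate_tracks(field: UpdraftField, cfg: IBMMConfig) -> list[Track]:
    """Simulate ``cfg.n_tracks`` independent tracks from the boundary."""
    starts = start_positions(field, cfg)
    return [
        simulate_track(field, starts[i], cfg, _track_rng(cfg.seed, i))
        for i in range(cfg.n_tracks)
    ]


def rasterize_tracks(tracks, field: UpdraftField) -> np.ndarray:
    """Per-cell count of recorded track positions (endpoints, incl. starts)."""
    grid = field.grid
    counts = np.zeros(grid.shape)
    for t in tracks:
        row, col = grid.fractional_index(t.positions[:, 0], t.positions[:, 1])
        r = np.round(row).astype(int)
        c = np.round(col).astype(int)
        ok = (r >= 0) & (r < grid.nrows) & (c >= 0) & (c < grid.ncols)
        np.add.at(counts, (r[ok], c[ok]), 1.0)
    return counts


def presence_map(field: UpdraftField, cfg: IBMMConfig, tracks=None) -> PresenceMap:
    """Smoothed relative presence density over many simulated tracks.

    Positions are rasterised to cell counts, smoothed with a Gaussian
    kernel (``cfg.smoothing_sigma`` cells, truncated at the boundary) and
    rescaled to [0, 1].  Deterministic for a fixed master seed.
    """
    if tracks is None:
        tracks = simulate_tracks(field, cfg)
    counts = rasterize_tracks(tracks, field)
    density = ndimage.gaussian_filter(counts, sigma=cfg.smoothing_sigma, mode="constant")
    peak = density.max()
    if peak > 0:
        density = density / peak
    total = int(sum(len(t.positions) for t in tracks))
    return PresenceMap(
        density=density,
        counts=counts,
        n_tracks=len(tracks),
        smoothing_sigma=cfg.smoothing_sigma,
        total_positions=total,
    )
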