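"""End-to-end runs: terrain -> updraft fields -> optional movement simulation.

`run_pipeline` executes every scenario x height combination of a
:class:`~orolift.config.RunConfig`, writes the resulting rasters and track
files, and returns (and writes) a JSON manifest with parameters, seed and
SHA-256 checksums of every artifact, so identical configurations are
verifiably reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from .config import RunConfig, SyntheticTerrainSpec
from .movement import IBMMConfig, presence_map, simulate_tracks
from .raster import load_dem, write_geotiff
from .terrain import ElevationGrid, generate_flat, generate_gaussian_ridge, generate_plane
from .updraft import UpdraftField, bo04_updraft, evve_updraft

__all__ = ["build_terrain", "run_pipeline", "tracks_to_dataframe", "tracks_to_geojson"]

logger = logging.getLogger("orolift.pipeline")

_COMPONENT_ORDER = ["w0", "f_h", "f_sx", "f_tc", "F"]


def build_terrain(spec: SyntheticTerrainSpec) -> ElevationGrid:
    """Instantiate the synthetic terrain described by a config block."""
    shape = (spec.nrows, spec.ncols)
    if spec.kind == "ridge":
        return generate_gaussian_ridge(
            shape, spec.dx, spec.peak_height, spec.width_sigma,
            ridge_azimuth=spec.azimuth, base_elevation=spec.base_elevation,
        )
    if spec.kind == "plane":
        return generate_plane(
            shape, spec.dx, spec.gradient, gradient_azimuth=spec.azimuth,
            base_elevation=spec.base_elevation,
        )
    return generate_flat(shape, spec.dx, elevation=spec.base_elevation)


def tracks_to_dataframe(tracks) -> pd.DataFrame:
    """Tracks as a long-format table (track_id, step_index, x, y, step_kind)."""
    rows = []
    for tid, t in enumerate(tracks):
        kinds = ("start",) + t.step_kinds
        for i, (pos, kind) in enumerate(zip(t.positions, kinds)):
            rows.append((tid, i, pos[0], pos[1], kind))
    return pd.DataFrame(rows, columns=["track_id", "step_index", "x", "y", "step_kind"])


def tracks_to_geojson(tracks) -> dict:
    """Tracks as a GeoJSON FeatureCollection of LineStrings (map metres)."""
    features = []
    for tid, t in enumerate(tracks):
        features.append({
            "type": "Feature",
            "properties": {"track_id": tid, "terminated_by": t.terminated_by},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in t.positions],
            },
        })
    return {"type": "FeatureCollection", "features": features}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _compute_field(grid, scenario, h, cfg: RunConfig) -> UpdraftField:
    if cfg.model == "evve":
        return evve_updraft(grid, scenario, h, sx_cfg=cfg.sx, clip_negative=cfg.clip_negative)
    return bo04_updraft(grid, scenario, h=h, clip_negative=cfg.clip_negative)


def run_pipeline(config: RunConfig) -> dict:
    """Run all scenario x height combinations and write artifacts.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.perf_counter()
    if config.dem_path is not None:
        logger.info("loading DEM from %s", config.dem_path)
        grid = load_dem(config.dem_path, fill_nodata=config.fill_nodata)
    else:
        logger.info("generating synthetic terrain: %s", config.synthetic.kind)
        grid = build_terrain(config.synthetic)
    logger.info(
        "terrain ready: %dx%d cells at %.1f m (%.2f s)",
        grid.nrows, grid.ncols, grid.dx, time.perf_counter() - t0,
    )

    files = []
    for si, scenario in enumerate(config.scenarios):
        for h in config.heights:
            t1 = time.perf_counter()
            field = _compute_field(grid, scenario, h, config)
            name = f"updraft_{config.model}_s{si}_wd{scenario.wdir:g}_v{scenario.v_ref:g}_h{h:g}.tif"
            path = os.path.join(config.out_dir, name)
            bands = [field.w] + [field.components[k] for k in _COMPONENT_ORDER if k in field.components]
            band_names = ["w"] + [k for k in _COMPONENT_ORDER if k in field.components]
            write_geotiff(path, np.stack(bands), grid.dx, grid.origin, band_names=band_names)
            files.append(path)
            logger.info(
                "scenario %d h=%g m: w min/mean/max = %.3f/%.3f/%.3f m/s (%.2f s)",
                si, h, field.w.min(), field.w.mean(), field.w.max(), time.perf_counter() - t1,
            )

            if config.ibmm is not None:
                t2 = time.perf_counter()
                ibmm = IBMMConfig(**{**config.ibmm.__dict__, "seed": config.seed})
                tracks = simulate_tracks(field, ibmm)
                pm = presence_map(field, ibmm, tracks=tracks)
                stem = os.path.splitext(path)[0]
                csv_path = stem + "_tracks.csv"
                tracks_to_dataframe(tracks).to_csv(csv_path, index=False)
                gj_path = stem + "_tracks.geojson"
                with open(gj_path, "w") as fh:
                    json.dump(tracks_to_geojson(tracks), fh)
                pm_path = stem + "_presence.tif"
                write_geotiff(pm_path, pm.density, grid.dx, grid.origin, band_names=["presence"])
                files += [csv_path, gj_path, pm_path]
                logger.info(
                    "scenario %d h=%g m: %d tracks, presence map done (%.2f s)",
                    si, h, len(tracks), time.perf_counter() - t2,
                )

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_outputs": len(files),
        "files": [
            {"path": os.path.relpath(p, config.out_dir), "sha256": _sha256(p)}
            for p in files
        ],
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %d artifacts in %s", len(files), config.out_dir)
    return manifest
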