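"""Simulated golden-eagle movement over a ridge updraft field.

1000 virtual birds are released along the northern boundary with a
southbound travel intent. Wherever the interpolated updraft one step ahead
exceeds the 0.85 m/s soaring threshold they follow the strongest lift;
elsewhere they take a directed random walk. The presence map shows how the
usable-updraft corridor along the ridge concentrates the simulated tracks.
"""
import numpy as np

from orolift import (
    IBMMConfig,
    WindScenario,
    evve_updraft,
    generate_gaussian_ridge,
    presence_map,
    simulate_tracks,
)

grid = generate_gaussian_ridge((101, 101), 30.0, peak_height=100.0, width_sigma=200.0)
field = evve_updraft(grid, WindScenario(wdir=270.0, v_ref=8.0), h=80.0, clip_negative=True)
print(f"usable updraft cells (> 0.85 m/s): {(field.w > 0.85).mean() * 100:.1f}% of domain")

cfg = IBMMConfig(phi=180.0, w_thr=0.85, step=30.0, n_tracks=1000, seed=42, start_edge="north")
tracks = simulate_tracks(field, cfg)
kinds = [k for t in tracks for k in t.step_kinds]
print(f"{len(tracks)} tracks, {len(kinds)} steps total, "
      f"{100 * sum(k == 'updraft' for k in kinds) / len(kinds):.1f}% updraft-seeking")

pm = presence_map(field, cfg, tracks=tracks)
inner = pm.density[10:-10, 10:-10]
r, c = np.unravel_index(inner.argmax(), inner.shape)
crest_col = (grid.ncols - 1) / 2
print(f"presence maximum: {abs(c + 10 - crest_col) * grid.dx:.0f} m from the ridge crest")
print(f"presence concentration (CV over interior): {inner.std() / inner.mean():.2f}")
# A zero-updraft field gives a diffuse band instead (CV ~ 0.1): run
# presence_map on a zero field to see the directed-random-walk limit.
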