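# Methods

This note documents the models implemented in `orolift`, the conventions
and numerical choices behind them, and what the synthetic test conditions
do and do not establish.

## Terrain representation

An `ElevationGrid` is a north-up, uniformly spaced raster of elevations in
metres. The origin is the map coordinate of the north-west corner of the
north-west cell (GDAL convention); cell centres are at
`x = x0 + (col + ½)·dx`, `y = y0 − (row + ½)·dx`, and the cell↔map mapping
round-trips exactly at centres. All azimuths are compass degrees
(0 = north, clockwise). Grids must be in a projected, metre-unit
coordinate system: every length in the model (search rays, windows,
kernels, step lengths) is metric, so geographic (degree) rasters are
rejected at load rather than silently mis-scaled.

**Slope and aspect.** Interior cells use the Horn 3×3 weighted
finite-difference stencil; the border ring falls back to one-sided
differences. Slope is `arctan|∇z|`; aspect is the azimuth of `−∇z`, i.e.
the direction the slope *face* points toward, so the baseline coefficient
is maximal when the wind direction (meteorological "from" convention)
equals the aspect. Exactly flat cells get slope 0 and, by convention,
aspect 0 — harmless because `sin θ = 0` already zeroes the coefficient
there.

**Height-dependent smoothing.** The corrected model differentiates a
smoothed terrain: an isotropic Gaussian kernel with
`σ(h) = min(0.8·h + 16, 300)` m, reflective boundaries. We blur the *DEM*
and then differentiate, rather than blurring slope and aspect separately:
averaging the circular aspect variable across its 0/360 wrap is
ill-defined, whereas differentiating the smoothed surface is not, and the
two descriptions coincide for small slopes. Reflective boundaries keep the
total elevation mass fixed and leave constant fields unchanged.

**Exposure/sheltering (Sx).** For each cell, the maximum elevation angle
`arctan((z_v − z_i)/distance)` to terrain sampled along a ray at distances
dx, 2·dx, … ≤ dmax (default 500 m), averaged over a fan of rays. Rays step
a constant dx with bilinear interpolation rather than walking rasterised
cells: that makes the quantity resolution-independent and trivially
matched by a brute-force oracle. The search azimuth is *flipped* downwind
(`A = (wdir + 180) mod 360`, fan half-width 15°, increment 5°, 7 rays), so
windward faces — terrain rising downwind of the cell — score positive and
feed `f_Sx = 1 + tan(Sx) > 1`. Rays are truncated at the grid edge (a ray
with no valid sample contributes 0), and an optional mask flags truncated
cells. Samples within 10⁻⁹ cells of the boundary count as inside: without
this tolerance, trigonometric rounding (cos 60° vs sin 150°) makes
boundary-grazing samples flicker in and out under 90° grid rotations and
breaks exact rotational equivariance.

**Terrain complexity.** Over the square window of side 500 m centred on
each cell (truncated at edges; the window half-width rounds to whole
cells, 510 m at 30 m resolution), `tc = (mean − min)/(max − min)` of the
elevations. It is invariant to shifting or positively scaling the
elevations and lies in [0, 1]; windows with relief below 10⁻⁶ m get
tc = 0, a convention needed because flat terrain never arises in the
fitting data but does in tests. The windowed mean uses a summed-area
table with exact truncated counts; the extrema use min/max filters with
nearest-edge padding, which replicates in-window cells and therefore
equals the truncated-window extrema.

## Updraft models

**Baseline (`bo04`).** `w = V·sin θ·cos(α − β)` on the raw DEM.
Height-independent. Because the multiplying speed is ambiguous in common
usage, `orolift` dimensionalises it with the same `V_ref` at 80 m AGL used
by the corrected model (configurable), which makes the two models directly
comparable.

**Corrected (`evve`).** Pipeline, at query height h AGL:

1. blur the DEM with σ(h); compute slope/aspect of the blurred surface;
2. `W0' = sin θ'·cos(α − β')` from the blurred metrics;
3. `f_h = (a·h² + b·h + c)·d^(−cos θ' + e) + f` with
   a = 4·10⁻⁵ m⁻², b = 2.8·10⁻³ m⁻¹, c = 0.8, d = 0.35, e = 0.095,
   f = −0.09, using the per-cell blurred slope (localized and continuous;
   it reduces to the feature-maximum behaviour near a crest). A warning is
   emitted outside h ∈ [30, 200] m, the range the surface fit covers, and
   a non-positive f_h raises (it is a divisor);
4. `f_Sx` and `f_tc = 1 + (h/40 m)·tc` on the **raw** DEM — both already
   integrate over ~500 m neighbourhoods, so smoothing them again would
   double-count the scale;
5. `w = V_ref · (f_Sx·f_tc/f_h) · W0'`.

All five component fields are retained on the returned `UpdraftField` for
inspection, testing and multi-band raster output. The model is meaningful
only where `W0' ≥ 0`: `clip_negative` zeroes and flags leeward cells, and
is the recommended setting when the field feeds the movement model (off by
default for raw field output). Not modelled: thermal/buoyant lift,
leeward recirculation and separated flow, non-neutral stratification.

## Movement model

A bird has an intended azimuth φ and takes constant steps (default 30 m).
Each step evaluates the updraft, bilinearly interpolated, at the five
candidates one step ahead at φ, φ±15°, φ±30°. If the best in-domain
candidate strictly exceeds the threshold `w_thr` (default 0.85 m/s, a
minimum-sink estimate for golden eagles) the bird moves there; otherwise
it draws one of the five uniformly (a directed random walk). Decisions the
underlying description leaves open, fixed here:

* **Argmax ties** go to the candidate closest to φ, then the lowest
  angular index — deterministic, and on a uniform above-threshold field it
  yields perfectly straight tracks. The bilinear interpolation is written
  in incremental form (base value plus weighted differences) so constant
  fields interpolate *exactly* and ties are genuine.
* **Random steps** reuse the same five forward candidates, keeping the
  fallback "directed".
* **Termination**: exit from the domain (an out-of-domain candidate, if
  drawn, becomes the final exit point) or a step cap (default
  3 × domain diagonal / step). If *all five* candidates are out of the
  domain the bird exits deterministically along φ (step kind `"exit"`).
* **Starts**: evenly spaced along a chosen boundary edge, with an optional
  seeded jitter.
* **Reproducibility**: track i's generator is derived from
  `SeedSequence(master_seed, spawn_key=(1, i))`, so runs are bit-identical
  under a fixed master seed and enlarging `n_tracks` never reshuffles
  earlier tracks.

The expected per-step progress of the zero-field walk along φ is
`step·(1 + 2·cos 15° + 2·cos 30°)/5 ≈ 0.9328·step`, used as a closed-form
check of the uniform fallback.

**Presence maps** count track positions (step endpoints, including the
start) per cell, smooth with a Gaussian kernel (default σ = 2 cells,
truncated at the boundary) and rescale to [0, 1]. Pre-smoothing mass
equals the recorded in-domain positions; each track loses at most its one
exit point.

## Synthetic terrain as study conditions

The generators produce what the estimator was designed around: Gaussian
ridges of controllable steepness and orientation (the parametric-study
shape), planes (analytic slope/aspect/Sx/tc fixtures) and flats
(zero-limit fixtures). Default study conditions used in tests, examples
and the acceptance script: a 100 m high, 200 m wide-sigma ridge on a 30 m
grid (max slope ≈ 17°, attached flow), an 8 m/s wind at the 80 m reference
height blowing orthogonally onto the ridge, heights spanning the
rotor-swept zone (40–180 m), and the movement defaults (0.85 m/s, 30 m
steps, 1000 tracks). Real terrain differs in ways the synthetic conditions
do not probe: heterogeneous multi-feature interaction (channeling between
features), DEM noise, slopes steep enough to separate the flow, and
non-neutral atmospheres. Passing tests therefore establish internal
correctness and the model's qualitative behaviour (height decay, windward
enhancement, corridor concentration), not field accuracy.

## Numerical conventions and tolerances

* Vectorised Sx and tc match naive triple-loop oracles to ≤ 10⁻¹²
  (radians / dimensionless) on 50×50 random grids.
* 90° rotational equivariance of the full pipelines is asserted at
  atol = 10⁻⁹ — "floating-point exact": separable filtering and
  trig-identity rounding preclude bit equality.
* Linearity in `V_ref` is exact (bitwise) because doubling is a power-of-two
  scaling.
* DEMs are written as float64 GeoTIFFs (bit-exact round trips); derived
  pipeline rasters as float32, with band names and nodata recorded in the
  file. GeoTIFF georeferencing uses ModelPixelScale/ModelTiepoint plus a
  minimal GeoKey directory; the ESRI ASCII grid is available as a
  plain-text alternative (metres by convention).
* The 500 m Sx reach and window, the 30° fan, 5° increment, the σ(h)
  schedule, the f_h constants, Λ = h/40 and the movement defaults are the
  published calibration of the method and are not free parameters here.

## Known limitations

* Windward-side validity only; negative-coefficient cells are at best
  flagged, never corrected.
* The height factor extrapolates poorly outside 30–200 m AGL (warned).
* Sx and tc near domain edges use truncated rays/windows; prefer DEMs
  padded ~500 m beyond the region of interest.
* The movement model is memoryless and perceives only one step ahead; it
  is an illustration of updraft-model sensitivity, not a calibrated
  behavioural model.
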