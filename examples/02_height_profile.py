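"""Height dependence of the corrected updraft model.

The baseline coefficient is two-dimensional: whatever height you query, the
field is the same. The corrected model smooths the terrain more aggressively
with height and divides by a height factor fitted on simulated flows, so the
windward peak decays as you climb through the rotor-swept zone.
"""
from orolift import WindScenario, bo04_updraft, evve_updraft, generate_gaussian_ridge

grid = generate_gaussian_ridge((121, 121), 30.0, peak_height=100.0, width_sigma=200.0)
scenario = WindScenario(wdir=270.0, v_ref=8.0)
west = (slice(20, 101), slice(0, 60))

b = bo04_updraft(grid, scenario)
print(f"baseline peak (any height): {b.w[west].max():.3f} m/s")
print("height AGL   corrected peak   usable for soaring (> 0.85 m/s)?")
for h in (40.0, 80.0, 120.0, 160.0, 180.0):
    f = evve_updraft(grid, scenario, h)
    peak = f.w[west].max()
    print(f"   {h:5.0f} m        {peak:.3f} m/s       {'yes' if peak > 0.85 else 'no'}")
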