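"""One seeded simulation run of the individual-based model.

A small lattice (31 x 31 patches) under the dry regime (350 mm per year,
one event per week) with the exudation trait active, run for two simulated
years.  Prints the per-species abundance and biomass trajectory and the
normalized difference (positive = tap-rooted plants ahead).
"""

from rhizocomp import ModelParams, initialize, normalized_difference, step

params = ModelParams(grid_shape=(31, 31), annual_precip_mm=350.0,
                     precip_interval_days=7, exudation_active=True)
state = initialize(params, seed=42)

print("day   tap_n  fib_n   tap_biomass  fib_biomass  norm_diff")
for day in range(1, 731):
    step(state)
    if day % 73 == 0:
        tap_n, fib_n = state.species_counts()
        tap_b, fib_b = state.species_biomass()
        nd = normalized_difference(tap_b, fib_b)
        print(f"{day:4d}  {tap_n:5d}  {fib_n:5d}   {tap_b:10.0f}  {fib_b:10.0f}   {nd:+.3f}")

print()
print("under the dry regime the hydrophobic topsoil starves fibrous recruits")
print("on tap-occupied patches and the normalized difference drifts positive.")
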