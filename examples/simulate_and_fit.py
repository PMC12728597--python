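"""Simulate a purification run and fit the two-component elution model.

Generates seven noisy replicates of the reference scenario (nanostructure
peak at 300 μL, staple peak at 650 μL, nine 100 μL fractions, 5% noise)
and fits the first replicate.  The fitted modes should land near the true
peak positions and r² should be close to 1.
"""

from gsecquant import default_scenario, fit_mixture, simulate_replicates

scenario = default_scenario(seed=42)
profiles = simulate_replicates(scenario)
profile = profiles[0]

print("fraction  volume_uL  concentration_ng_per_uL")
for f, v, c in zip(profile.fractions, profile.volumes_uL, profile.concentrations):
    print(f"{f:>8d} {v:>10.0f} {c:>24.4f}")

fit = fit_mixture(profile, fraction_volume_uL=scenario.column_spec.fraction_volume_uL)
t, s = fit.component_target, fit.component_contaminant
print(f"\nnanostructure peak: mode {t.mode_uL:.1f} μL, sigma {t.sigma:.3f}, mass {t.alpha:.0f} ng")
print(f"staple peak:        mode {s.mode_uL:.1f} μL, sigma {s.sigma:.3f}, mass {s.alpha:.0f} ng")
print(f"r² = {fit.r_squared:.6f}")
print("\nThe modes recover the true 300/650 μL peak positions within a few μL")
print("despite 5% measurement noise on nine points.")
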