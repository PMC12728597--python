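"""Peak resolution and comparison against the generator's analytic truth.

Computes the FWHM-based resolution of the fitted peaks and checks the
fitted per-fraction purity against the exact values implied by the true
simulation components.
"""

from gsecquant import (
    default_scenario,
    fit_mixture,
    fraction_interval,
    fraction_purity,
    resolution,
    scenario_truth,
    simulate_profile,
)

scenario = default_scenario(seed=3)
profile = simulate_profile(scenario, 1)
fit = fit_mixture(profile, fraction_volume_uL=100.0)

res = resolution(fit)
print(f"peak 1 at {res.t_r1:.1f} μL (FWHM {res.w_half_1:.1f} μL)")
print(f"peak 2 at {res.t_r2:.1f} μL (FWHM {res.w_half_2:.1f} μL)")
print(f"resolution Rs = 2·Δt / (w1 + w2) = {res.rs:.3f}")
print("Rs ≈ 1.4 means the nanostructure and staple peaks are well separated")
print("but not baseline-resolved — overlapping mass shows up as purity < 1.\n")

truth = scenario_truth(scenario)
print("fraction   fitted purity   analytic purity")
for i in (2, 3, 4, 5):
    a, b = fraction_interval(i + 1, scenario.column_spec)
    fitted = fraction_purity(fit, max(a, 1e-12), b)
    print(f"{i + 1:>8d}   {fitted:13.4f}   {truth.fraction_purity[i]:15.4f}")
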