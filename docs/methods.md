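# Methods

## Model

A size-exclusion elution profile is modeled as the sum of two log-normal
densities in elution volume, each scaled by a mass constant:

y(x) = α₁ f(x; μ₁, σ₁) + α₂ f(x; μ₂, σ₂),  f(x; μ, σ) = exp(−(ln x − μ)²/2σ²) / (x σ √2π)

with `ln` the natural logarithm throughout (the conventional log-normal
parameterization; a base-10 convention would only rescale μ and σ, but a
single convention has to be fixed and this is it). Since concentration
(ng/μL) integrated over volume (μL) is mass (ng), α is the component's
total eluted mass. The log-normal shape captures the right-skewed tailing
of gravity-flow elution peaks; it is an empirical peak shape, not a
mechanistic column model.

Component identity: in size exclusion the large species elutes first, so
the component with the smaller mode `exp(μ − σ²)` is labeled the target
(nanostructures) and the larger-mode one the contaminant (staples). The
assignment is configurable (`FitOptions.target_is_smaller_mode`) for
separations with the opposite order. Exactly equal modes are ordered by
smaller σ and the fit is flagged `poorly_identified`.

## Coordinates and units

Units are fixed internally at μL, ng/μL and ng; readers convert on
ingest. Fraction *n* spans the elution interval ((n−1)·Vf, n·Vf] and its
measurement is placed at the **end** of the fraction, x = n·Vf, so that
with 100 μL fractions the reading of fraction 3 sits at 300 μL — the
axis users of these columns expect. A midpoint convention is available.
Elution volume counts eluent only; the loading volume is not added. That
choice is not forced by anything in the data model — with point sampling
a constant multiplicative shift of the axis only shifts both μ — and the
sensitivity can be probed by comparing conventions.

Concentrations are accepted as mass concentrations; conversion from raw
A260 absorbance (e.g. the 50 ng·cm/μL double-stranded DNA factor) is
deliberately out of scope.

## Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) on the plain residuals (observed − model), uniform
weighting by default. Defaults: σ ∈ [10⁻³, 2], μ within one log-unit of
the observed volume range, α ∈ [0, 10 × total measured mass], parameter
and cost tolerances 10⁻¹⁰, 1000 iterations per parameter.

Initialization is a deterministic multi-start rather than random
restarts, so the fitting path needs no seed: the mass-weighted volume
distribution is split at the 0.3–0.7 quantiles with per-side log-moment
estimates of (μ, σ) and trapezoid-AUC estimates of α; two
single-component-dominant starts cover degenerate (one-species)
profiles; and when the observed profile has two or more interior local
maxima their positions seed an additional start. The lowest-RSS
converged solution wins. On noiseless 9-point profiles from known
parameters this recovers all six parameters to machine precision; at 5%
noise the target μ is recovered to well under 2% mean absolute relative
error.

Per-replicate fitting is the default so that every derived metric gets
an across-replicate mean ± SD (sample SD, n−1 denominator; 0 for a
single replicate). A pooled mode fits the across-replicate mean profile
instead, with residuals weighted by inverse across-replicate SD where it
is positive; whether per-replicate or pooled fitting better matches any
given published curve is left to the user — both are provided, neither
asserted.

## Metrics

* **Interval mass** of a component: α(F(b) − F(a)) with F the log-normal
  CDF via `scipy.special.ndtr` (abs. accuracy ≪ 10⁻¹²).
* **Purity** of an interval: target mass over total mass in that
  interval. Purity is model-based only; without deconvolution the raw
  readings cannot apportion mass between species. Pooled purity over
  several fractions is the single-integral union-interval ratio
  (mass-weighted), not a mean of per-fraction purities.
* **Measured yield**: recovered spectrophotometer mass ÷ loaded target
  mass. Values above 1 are genuine (staple co-elution inflates the raw
  mass) and are reported with a `yield_exceeds_one` flag, never clipped.
  **Model yield** (target AUC captured ÷ α₁) is reported alongside.
* **Peak mode**: the closed form exp(μ − σ²).
* **FWHM**: the two roots of f(x) = f(mode)/2, located by bracketed
  Brent root finding on each side of the mode (bracket shrunk/grown
  geometrically until the density falls below half max), absolute
  tolerance 10⁻⁹ μL. The closed form
  2·exp(μ − σ²)·sinh(σ√(2 ln 2)) serves as an independent oracle in the
  tests, which agree to ≤ 10⁻⁸ relative over μ ∈ [ln 50, ln 2000],
  σ ∈ [0.02, 1.5].
* **Resolution**: Rs = 2(t_R2 − t_R1)/(w½,1 + w½,2) on the fitted peak
  maxima and FWHMs. This keeps the factor 2 with half-height widths;
  note it differs from the pharmacopoeial convention
  (1.18·Δt/(w½,1+w½,2)) by a factor ≈ 1.7, so values are not directly
  comparable across conventions.
* **Pool optimization**: exhaustive search over all contiguous fraction
  intervals for maximal model yield subject to a purity floor, ties
  broken by fewer fractions then earlier start. At collection scale
  (N ≲ 20 fractions, O(N²) intervals) enumeration is exact and
  instantaneous; no heuristic is involved.
* **Gel normalization**: each species' band-intensity row divided by its
  total ("normalized to 1" read as unit total, giving a fractional
  elution distribution); a unit-maximum option is provided since both
  readings of that phrase occur in practice.

## Synthetic generator

`synthetic.default_scenario` encodes the reference conditions: a 0.8 mL
column loaded with 50 μL and eluted in nine 100 μL fractions; target
component mode 300 μL (σ = 0.15, α = 600 ng) and contaminant mode
650 μL (σ = 0.25, α = 400 ng), placing the nanostructure peak in
fractions 3–4 with late-eluting staples; seven replicates; 5%
multiplicative noise. The 600/400 mass split reflects that folding
reactions carry a several-fold staple excess of which only part elutes
in the collected window, and σ values give peak widths (FWHM ≈ 105 and
375 μL) consistent with one-to-few-fraction-wide peaks.

Observed concentrations are max(0, true·(1+ε)) with ε ~ N(0, cv²) —
multiplicative truncated-Gaussian noise mimicking spectrophotometric
error, with cv = 5% as a realistic instrument-plus-pipetting figure.
Truncation at zero introduces a slight positive bias at near-zero
concentrations. Each (replicate, fraction) pair uses its own substream
seeded by the tuple (seed, replicate, fraction), so enlarging a study
never perturbs earlier draws and identical scenarios are bit-identical.

Point sampling (density evaluated at the convention volume) is the
default forward model, matching how per-fraction readings are fitted as
points; an integrated mode (interval mass ÷ fraction volume) exists to
probe the coordinate-convention sensitivity — with 100 μL fractions the
two differ by a few percent near the narrow target peak.

`scenario_truth` computes the exact per-fraction and pooled purity and
yield from the true components; it is the oracle for the end-to-end
tests: the noiseless pipeline reproduces it to ≤ 10⁻⁴ absolute, and at
5% noise the mean fitted pooled purity over the two peak fractions stays
within 3 percentage points over 20 Monte-Carlo repetitions.

What the generator does **not** emulate: baseline drift, column-to-column
geometry variation, fraction-volume pipetting error, a third species
(e.g. free protein or aggregates), and deviation of real band shapes
from log-normal. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not that real
elution peaks are log-normal.

## Numerical choices and edge cases

* Fits are deterministic end-to-end; JSON reports round floats to 12
  significant digits and contain no timestamps, so repeat runs are
  byte-identical.
* Purity on an interval carrying < 10⁻¹² of the total fitted mass raises
  an undefined-metric error rather than returning noise from a 0/0.
* Resolution requires both α > 0; a single-species fit has no pairwise
  resolution.
* Flat (all-equal) profiles produce valid, non-degenerate starting
  candidates; σ estimates are floored at 0.02 before clipping into
  bounds.
* Aggregation shortcuts exactly-identical replicate values to SD = 0 to
  avoid floating-point dust in the "no variance" case.
* Measured yield exceeding 1 is flagged, not an error (see above).

## Problem sizes

Default analyses operate on 9-fraction, 7-replicate data sets; the
validation suite uses up to 400 simulated replicates for noise-model
checks, 50×50 parameter grids for the peak-descriptor oracles, 100
randomized fixtures for pooling optimality, and 20 Monte-Carlo
repetitions (140 fits) for stochastic-recovery checks — sizes chosen so
the full suite completes in about a minute while keeping Monte-Carlo
error comfortably below the tested tolerances.

## Known limitations

Exactly two components; no baseline subtraction; no absorbance-to-mass
conversion; no vendor chromatography formats; gel analysis starts from
numeric band-intensity tables, not images. The log-shift equivariance of
the fit holds with α scaling along (rescaling the volume axis by k
rescales the density by 1/k, so α must absorb k to preserve
concentration values) — a property worth knowing when comparing columns
of different geometry.
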