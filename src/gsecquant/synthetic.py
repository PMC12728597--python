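"""Synthetic elution-profile generator with known ground truth.

The generator is the forward model of the analysis: two log-normal
elution components (nanostructures eluting early, staples late) sampled
at discrete fraction volumes, with multiplicative spectrophotometric
measurement noise.  Because the true component parameters are known,
every analysis result (fitted parameters, purity, yield, resolution,
pool choice) can be compared against the analytic truth computed by
:func:`scenario_truth`.

The default scenario mirrors the small-scale purification setup: a
0.8 mL column eluted in nine 100 μL fractions, nanostructure peak at
300 μL and staple peak at 650 μL, 5% concentration noise, seven
replicates.

Randomness is strictly reproducible: each (replicate, fraction) pair
draws from its own substream derived from ``(seed, replicate, fraction)``
by a counter scheme, so adding replicates or fractions never perturbs
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .metrics import component_mass_on_interval
from .mixture import LogNormalComponent, mixture_value
from .profile_io import ColumnSpec, ElutionProfile, fraction_interval, fraction_to_volume

__all__ = ["SimulationScenario", "default_scenario", "simulate_profile",
           "simulate_replicates", "ScenarioTruth", "scenario_truth"]


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth description of a simulated purification run.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    measurement noise: observed = max(0, true × (1 + ε)) with
    ε ~ N(0, noise_cv²), truncated at zero concentration.
    ``sampling_mode`` controls the forward model: ``point`` evaluates the
    mixture density at the convention elution volume of each fraction
    (matching how per-fraction readings are fitted as points), while
    ``integrated`` uses the exact in-fraction mass divided by the fraction
    volume.
    """

    component_target: LogNormalComponent
    component_contaminant: LogNormalComponent
    column_spec: ColumnSpec = ColumnSpec()
    noise_cv: float = 0.05
    n_replicates: int = 7
    seed: int = 0
    sampling_mode: str = "point"
    volume_convention: str = "end"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.sampling_mode not in ("point", "integrated"):
            raise ValidationError(f"unknown sampling_mode {self.sampling_mode!r}")


def default_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """The package's reference scenario.

    Nanostructure component with mode 300 μL (σ = 0.15, α = 600 ng) and
    staple component with mode 650 μL (σ = 0.25, α = 400 ng), nine
    100 μL fractions, 5% noise, seven replicates.
    """
    scenario = SimulationScenario(
        component_target=LogNormalComponent.from_mode(300.0, 0.15, 600.0),
        component_contaminant=LogNormalComponent.from_mode(650.0, 0.25, 400.0),
        column_spec=ColumnSpec(),
        noise_cv=0.05,
        n_replicates=7,
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


def _true_concentrations(scenario: SimulationScenario) -> tuple[np.ndarray, np.ndarray]:
    spec = scenario.column_spec
    fractions = np.arange(1, spec.n_fractions + 1)
    volumes = np.array(
        [fraction_to_volume(int(f), spec, scenario.volume_convention) for f in fractions]
    )
    if scenario.sampling_mode == "point":
        true = np.asarray(
            mixture_value(scenario.component_target, scenario.component_contaminant, volumes)
        )
    else:
        true = np.empty(spec.n_fractions)
        for i, f in enumerate(fractions):
            a, b = fraction_interval(int(f), spec)
            mass = component_mass_on_interval(
                scenario.component_target, max(a, 1e-12), b
            ) + component_mass_on_interval(scenario.component_contaminant, max(a, 1e-12), b)
            true[i] = mass / spec.fraction_volume_uL
    return volumes, true


def simulate_profile(scenario: SimulationScenario, replicate_index: int) -> ElutionProfile:
    """One noisy replicate of the scenario, as an :class:`ElutionProfile`.

    Deterministic: the same scenario, seed and replicate index always
    produce bit-identical concentrations.  The profile's ``input_mass_ng``
    is set to the target component's true α, so measured yield is defined
    relative to the true loaded nanostructure mass.
    """
    if not (1 <= replicate_index <= scenario.n_replicates):
        raise ValidationError(
            f"replicate_index must lie in [1, {scenario.n_replicates}], got {replicate_index}"
        )
    volumes, true = _true_concentrations(scenario)
    obs = np.empty_like(true)
    for i in range(true.size):
        # one substream per (seed, replicate, fraction): stable under growth
        rng = np.random.default_rng([scenario.seed, replicate_index, i + 1])
        eps = rng.normal(0.0, scenario.noise_cv) if scenario.noise_cv > 0 else 0.0
        obs[i] = max(0.0, true[i] * (1.0 + eps))
    return ElutionProfile(
        replicate_id=f"sim-{replicate_index}",
        fractions=np.arange(1, scenario.column_spec.n_fractions + 1),
        volumes_uL=volumes,
        concentrations=obs,
        input_mass_ng=scenario.component_target.alpha,
    )


def simulate_replicates(scenario: SimulationScenario) -> list[ElutionProfile]:
    """All ``n_replicates`` profiles of the scenario."""
    return [simulate_profile(scenario, r) for r in range(1, scenario.n_replicates + 1)]


@dataclass(frozen=True)
class ScenarioTruth:
    """Analytic per-fraction and pooled purity/yield of a scenario.

    Arrays are indexed by fraction (entry i = fraction i+1).  ``pool``
    returns the exact union-interval purity and model yield of any
    contiguous fraction run — the oracle the fitted pipeline is compared
    against.
    """

    scenario: SimulationScenario
    fraction_target_mass: np.ndarray
    fraction_contaminant_mass: np.ndarray

    @property
    def fraction_purity(self) -> np.ndarray:
        tot = self.fraction_target_mass + self.fraction_contaminant_mass
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.fraction_target_mass / tot, np.nan)

    @property
    def fraction_model_yield(self) -> np.ndarray:
        return self.fraction_target_mass / self.scenario.component_target.alpha

    def pool(self, first: int, last: int) -> tuple[float, float]:
        """(purity, model yield) of the union interval of fractions first..last."""
        spec = self.scenario.column_spec
        if not (1 <= first <= last <= spec.n_fractions):
            raise ValidationError("pool bounds out of range")
        a = max(fraction_interval(first, spec)[0], 1e-12)
        b = fraction_interval(last, spec)[1]
        m_t = component_mass_on_interval(self.scenario.component_target, a, b)
        m_c = component_mass_on_interval(self.scenario.component_contaminant, a, b)
        purity = m_t / (m_t + m_c) if (m_t + m_c) > 0 else float("nan")
        return purity, m_t / self.scenario.component_target.alpha

    def peak_fractions(self, k: int = 2) -> tuple[int, ...]:
        """The contiguous run of k fractions holding the most target mass."""
        masses = self.fraction_target_mass
        best_start = max(
            range(masses.size - k + 1), key=lambda s: masses[s : s + k].sum()
        )
        return tuple(range(best_start + 1, best_start + k + 1))


def scenario_truth(scenario: SimulationScenario) -> ScenarioTruth:
    """Exact per-fraction target/contaminant masses from the true components."""
    spec = scenario.column_spec
    m_t = np.empty(spec.n_fractions)
    m_c = np.empty(spec.n_fractions)
    for i in range(spec.n_fractions):
        a, b = fraction_interval(i + 1, spec)
        a = max(a, 1e-12)
        m_t[i] = component_mass_on_interval(scenario.component_target, a, b)
        m_c[i] = component_mass_on_interval(scenario.component_contaminant, a, b)
    return ScenarioTruth(
        scenario=scenario,
        fraction_target_mass=m_t,
        fraction_contaminant_mass=m_c,
    )
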