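import numpy as np
import pytest

from gsecquant import (
    ColumnSpec,
    ElutionProfile,
    LogNormalComponent,
    default_scenario,
    simulate_profile,
)


@pytest.fixture
def column_spec() -> ColumnSpec:
    return ColumnSpec()  # 0.8 mL CV, 50 μL LV, 9 × 100 μL fractions


@pytest.fixture
def target_component() -> LogNormalComponent:
    return LogNormalComponent.from_mode(300.0, 0.15, 600.0)


@pytest.fixture
def contaminant_component() -> LogNormalComponent:
    return LogNormalComponent.from_mode(650.0, 0.25, 400.0)


@pytest.fixture
def noiseless_profile() -> ElutionProfile:
    """Nine noiseless fraction readings from the reference two-component truth."""
    scenario = default_scenario(noise_cv=0.0, n_replicates=1)
    return simulate_profile(scenario, 1)


@pytest.fixture
def noisy_scenario():
    return default_scenario(seed=20260920)


def well_separated_fit():
    """A MixtureFit-like object with well-separated known components."""
    from gsecquant import MixtureFit

    return MixtureFit(
        component_target=LogNormalComponent.from_mode(300.0, 0.15, 600.0),
        component_contaminant=LogNormalComponent.from_mode(650.0, 0.25, 400.0),
        rss=0.0,
        r_squared=1.0,
        converged=True,
        n_points=9,
    )


@pytest.fixture
def known_fit():
    return well_separated_fit()
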