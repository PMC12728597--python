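"""Tests for purity, yield, FWHM/resolution and pooling metrics.

Independent oracles: adaptive quadrature of the scaled density for
interval masses, the closed form 2·exp(mu−sigma²)·sinh(sigma·sqrt(2 ln 2))
for the FWHM, and scipy.stats.lognorm plus explicit enumeration for the
pooling search.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from gsecquant import (
    ColumnSpec,
    ConfigurationError,
    ElutionProfile,
    GelBandTable,
    LogNormalComponent,
    MixtureFit,
    UndefinedMetricError,
    ValidationError,
    aggregate_replicates,
    build_report,
    component_mass_on_interval,
    fraction_interval,
    fraction_purity,
    fwhm_numeric,
    measured_yield,
    normalize_gel_bands,
    peak_mode,
    pool_optimize,
    resolution,
    resolution_from_peaks,
)


def fwhm_closed_form(mu: float, sigma: float) -> float:
    """Analytic FWHM of the log-normal density.

    Solving ln f(x) = ln f(mode) − ln 2 as a quadratic in ln x gives
    roots mu − sigma² ± sigma·sqrt(2 ln 2), hence the width
    2·exp(mu − sigma²)·sinh(sigma·sqrt(2 ln 2)).
    """
    return 2.0 * math.exp(mu - sigma**2) * math.sinh(sigma * math.sqrt(2 * math.log(2)))


class TestComponentMass:
    def test_total_mass_is_alpha(self, target_component):
        assert component_mass_on_interval(target_component, 1e-12, 1e9) == pytest.approx(
            target_component.alpha, rel=1e-6
        )

    def test_log_symmetric_interval(self):
        c = LogNormalComponent(mu=math.log(300), sigma=0.2, alpha=600.0)
        cc = 0.35
        expected = 600.0 * (2 * stats.norm.cdf(cc / 0.2) - 1)
        got = component_mass_on_interval(c, math.exp(c.mu - cc), math.exp(c.mu + cc))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        c = LogNormalComponent(mu=math.log(300), sigma=0.2, alpha=600.0)
        oracle, _ = quad(c.value, 200.0, 300.0, epsabs=1e-12, epsrel=1e-12)
        assert component_mass_on_interval(c, 200.0, 300.0) == pytest.approx(oracle, rel=1e-8)

    def test_rejects_inverted_interval(self, target_component):
        with pytest.raises(ValidationError):
            component_mass_on_interval(target_component, 300.0, 200.0)

    def test_mass_conservation_over_partition(self, target_component):
        edges = np.linspace(1e-9, 2000.0, 2001)
        partial = sum(
            component_mass_on_interval(target_component, a, b)
            for a, b in zip(edges[:-1], edges[1:])
        )
        tail = target_component.alpha * (1 - target_component.cdf(edges[-1]))
        assert partial + tail == pytest.approx(target_component.alpha, rel=1e-9)


class TestFractionPurity:
    def test_far_left_interval_is_pure_target(self, known_fit):
        assert fraction_purity(known_fit, 100.0, 250.0) > 0.999

    def test_identical_components_give_half(self):
        c = LogNormalComponent(mu=math.log(400), sigma=0.2, alpha=300.0)
        fit = MixtureFit(c, c, 0.0, 1.0, True, 9)
        assert fraction_purity(fit, 200.0, 600.0) == pytest.approx(0.5, rel=1e-12)

    def test_matches_quadrature_ratio(self, known_fit):
        t, c = known_fit.component_target, known_fit.component_contaminant
        m_t, _ = quad(t.value, 200.0, 300.0, epsabs=1e-13, epsrel=1e-13)
        m_c, _ = quad(c.value, 200.0, 300.0, epsabs=1e-13, epsrel=1e-13)
        assert fraction_purity(known_fit, 200.0, 300.0) == pytest.approx(
            m_t / (m_t + m_c), rel=1e-8
        )

    def test_empty_interval_raises(self, known_fit):
        with pytest.raises(UndefinedMetricError):
            fraction_purity(known_fit, 1e6, 2e6)

    def test_monotone_decrease_toward_contaminant(self, known_fit):
        # widening the window from the target mode toward the contaminant
        # mode never increases purity for separated, ordered components
        purities = [fraction_purity(known_fit, 250.0, b) for b in np.linspace(350, 900, 12)]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(purities, purities[1:]))


class TestMeasuredYield:
    def _profile(self, conc, input_mass=600.0):
        n = len(conc)
        return ElutionProfile(
            "r1", np.arange(1, n + 1), np.arange(1, n + 1) * 100.0, conc, input_mass
        )

    def test_full_recovery_single_fraction(self, column_spec):
        profile = self._profile([0, 0, 6.0, 0, 0], input_mass=600.0)
        assert measured_yield(profile, [3], column_spec) == pytest.approx(1.0)

    def test_nothing_eluted(self, column_spec):
        profile = self._profile([0.0] * 5)
        assert measured_yield(profile, [1, 2, 3], column_spec) == 0.0

    def test_can_exceed_one_without_clipping(self, column_spec):
        profile = self._profile([0, 0, 8.0, 0, 0], input_mass=600.0)
        assert measured_yield(profile, [3], column_spec) == pytest.approx(800.0 / 600.0)

    def test_missing_input_mass_raises(self, column_spec):
        profile = self._profile([1.0] * 5, input_mass=None)
        with pytest.raises(ConfigurationError):
            measured_yield(profile, [1], column_spec)

    def test_unknown_fraction_raises(self, column_spec):
        profile = self._profile([1.0] * 5)
        with pytest.raises(ValidationError):
            measured_yield(profile, [99], column_spec)


class TestPeakModeAndFwhm:
    def test_mode_constructed_inverse(self):
        sigma = 0.3
        c = LogNormalComponent(mu=math.log(300) + sigma**2, sigma=sigma, alpha=1.0)
        assert peak_mode(c) == pytest.approx(300.0, rel=1e-14)

    def test_mode_matches_numerical_maximum(self):
        from scipy.optimize import minimize_scalar

        c = LogNormalComponent(mu=5.7, sigma=0.1, alpha=1.0)
        res = minimize_scalar(
            lambda u: -(-u - (u - c.mu) ** 2 / (2 * c.sigma**2)),
            bounds=(c.mu - 2, c.mu + 2),
            method="bounded",
            options={"xatol": 1e-13},
        )
        assert peak_mode(c) == pytest.approx(math.exp(res.x), rel=1e-10)

    @given(
        mu=st.floats(math.log(50), math.log(2000)),
        sigma=st.floats(0.02, 1.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fwhm_equals_closed_form(self, mu, sigma):
        c = LogNormalComponent(mu=mu, sigma=sigma, alpha=1.0)
        assert fwhm_numeric(c) == pytest.approx(fwhm_closed_form(mu, sigma), rel=1e-8)

    def test_fwhm_example_value(self):
        mu, sigma = math.log(300) + 0.01, 0.1
        c = LogNormalComponent(mu=mu, sigma=sigma, alpha=1.0)
        expected = 2 * 300.0 * math.sinh(0.1 * math.sqrt(2 * math.log(2)))
        assert fwhm_numeric(c) == pytest.approx(expected, rel=1e-8)

    def test_fwhm_independent_of_alpha(self):
        a = LogNormalComponent(mu=5.7, sigma=0.2, alpha=1.0)
        b = LogNormalComponent(mu=5.7, sigma=0.2, alpha=1e4)
        assert fwhm_numeric(a) == pytest.approx(fwhm_numeric(b), rel=1e-12)


class TestResolution:
    def test_formula_arithmetic(self):
        assert resolution_from_peaks(300.0, 600.0, 70.0, 170.0) == pytest.approx(2.5)

    def test_identical_components_zero_resolution(self):
        c = LogNormalComponent(mu=5.7, sigma=0.2, alpha=10.0)
        fit = MixtureFit(c, c, 0.0, 1.0, True, 9)
        assert resolution(fit).rs == 0.0

    def test_matches_analytic_composition(self, known_fit):
        t, c = known_fit.component_target, known_fit.component_contaminant
        t1, t2 = t.mode_uL, c.mode_uL
        w1 = fwhm_closed_form(t.mu, t.sigma)
        w2 = fwhm_closed_form(c.mu, c.sigma)
        expected = 2 * (t2 - t1) / (w1 + w2)
        assert resolution(known_fit).rs == pytest.approx(expected, rel=1e-8)

    def test_invariant_under_common_alpha_scaling_and_relabeling(self, known_fit):
        t, c = known_fit.component_target, known_fit.component_contaminant
        scaled = MixtureFit(replace(t, alpha=7 * t.alpha), replace(c, alpha=7 * c.alpha),
                            0.0, 1.0, True, 9)
        swapped = MixtureFit(c, t, 0.0, 1.0, True, 9)
        base = resolution(known_fit)
        assert resolution(scaled).rs == pytest.approx(base.rs, rel=1e-12)
        res_swapped = resolution(swapped)
        assert res_swapped.rs == pytest.approx(base.rs, rel=1e-12)
        assert res_swapped.t_r1 <= res_swapped.t_r2

    def test_zero_alpha_component_raises(self, target_component):
        zero = LogNormalComponent(mu=6.5, sigma=0.25, alpha=0.0)
        fit = MixtureFit(target_component, zero, 0.0, 1.0, True, 9)
        with pytest.raises(UndefinedMetricError):
            resolution(fit)


def brute_force_pool(fit, spec, min_purity):
    """Independent enumeration using scipy.stats.lognorm interval masses."""
    def masses(comp, a, b):
        d = stats.lognorm(comp.sigma, scale=math.exp(comp.mu))
        return comp.alpha * (d.cdf(b) - d.cdf(a))

    best, best_key = (), None
    for start in range(1, spec.n_fractions + 1):
        for end in range(start, spec.n_fractions + 1):
            a, b = (start - 1) * spec.fraction_volume_uL, end * spec.fraction_volume_uL
            m_t = masses(fit.component_target, a, b)
            m_c = masses(fit.component_contaminant, a, b)
            if m_t + m_c < 1e-12 * (fit.component_target.alpha + fit.component_contaminant.alpha):
                continue
            purity = m_t / (m_t + m_c)
            if purity + 1e-15 < min_purity:
                continue
            key = (m_t / fit.component_target.alpha, -(end - start + 1), -start)
            if best_key is None or key > best_key:
                best, best_key = tuple(range(start, end + 1)), key
    return best


class TestPoolOptimize:
    def test_no_constraint_returns_full_range(self, known_fit, column_spec):
        assert pool_optimize(known_fit, column_spec, 1e-9) == tuple(range(1, 10))

    def test_unattainable_purity_returns_empty(self, column_spec):
        c = LogNormalComponent(mu=math.log(400), sigma=0.2, alpha=300.0)
        fit = MixtureFit(c, c, 0.0, 1.0, True, 9)  # purity 0.5 everywhere
        assert pool_optimize(fit, column_spec, 0.99) == ()

    def test_high_purity_pool_covers_target_mode(self, known_fit, column_spec):
        pool = pool_optimize(known_fit, column_spec, 0.99)
        assert pool  # attainable for separated components
        assert 3 in pool  # target mode at 300 μL lies in fraction 3
        assert pool == brute_force_pool(known_fit, column_spec, 0.99)

    def test_equals_exhaustive_enumeration_on_random_fixtures(self, column_spec):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m1 = rng.uniform(150, 450)
            m2 = m1 * rng.uniform(1.2, 3.0)
            s1, s2 = rng.uniform(0.05, 0.5, 2)
            a1, a2 = rng.uniform(50, 1000, 2)
            fit = MixtureFit(
                LogNormalComponent.from_mode(m1, s1, a1),
                LogNormalComponent.from_mode(m2, s2, a2),
                0.0, 1.0, True, 9,
            )
            min_purity = rng.uniform(0.5, 0.999)
            assert pool_optimize(fit, column_spec, min_purity) == brute_force_pool(
                fit, column_spec, min_purity
            )


class TestAggregateReplicates:
    def _report(self, conc, spec, fit, pool=(3, 4)):
        n = len(conc)
        profile = ElutionProfile(
            "r", np.arange(1, n + 1), np.arange(1, n + 1) * 100.0, conc, 600.0
        )
        return build_report(profile, fit, spec, pool)

    def test_identical_reports_have_zero_sd(self, known_fit, column_spec):
        conc = np.asarray(known_fit.value(np.arange(1, 10) * 100.0))
        reports = [self._report(conc, column_spec, known_fit) for _ in range(3)]
        summary = aggregate_replicates(reports)
        for entry in summary.per_fraction.values():
            for mean, sd in entry.values():
                assert sd == 0.0
        assert summary.pooled["model_purity"][1] == 0.0

    def test_two_point_sample_sd(self, known_fit, column_spec):
        conc1 = np.zeros(9); conc1[2] = 3.0   # fraction-3 yield 0.5 of 600 ng
        conc2 = np.zeros(9); conc2[2] = 4.2   # fraction-3 yield 0.7
        r1 = self._report(conc1, column_spec, known_fit, pool=(3,))
        r2 = self._report(conc2, column_spec, known_fit, pool=(3,))
        summary = aggregate_replicates([r1, r2])
        mean, sd = summary.per_fraction[3]["measured_yield"]
        assert mean == pytest.approx(0.6)
        assert sd == pytest.approx(math.sqrt(((0.5 - 0.6) ** 2 + (0.7 - 0.6) ** 2) / 1))

    def test_single_report_sd_zero(self, known_fit, column_spec):
        conc = np.asarray(known_fit.value(np.arange(1, 10) * 100.0))
        summary = aggregate_replicates([self._report(conc, column_spec, known_fit)])
        assert summary.n_replicates == 1
        assert all(sd == 0.0 for _, sd in summary.pooled.values())

    def test_mismatched_fraction_sets_rejected(self, known_fit, column_spec):
        conc = np.ones(9)
        r1 = self._report(conc, column_spec, known_fit)
        short = ElutionProfile("s", np.arange(1, 6), np.arange(1, 6) * 100.0,
                               np.ones(5), 600.0)
        r2 = build_report(short, known_fit, column_spec, (3, 4))
        with pytest.raises(ValidationError):
            aggregate_replicates([r1, r2])


class TestGelNormalization:
    def _table(self, rows):
        arr = np.asarray(rows, dtype=float)
        return GelBandTable(
            species=tuple(f"s{i}" for i in range(arr.shape[0])),
            fractions=np.arange(1, arr.shape[1] + 1),
            intensities=arr,
        )

    def test_unit_total_per_species(self):
        out = normalize_gel_bands(self._table([[2, 2, 0, 0], [1, 1, 1, 1]]))
        assert np.allclose(out.intensities[0], [0.5, 0.5, 0, 0])
        assert np.allclose(out.intensities.sum(axis=1), 1.0, atol=1e-12)

    def test_idempotent(self):
        once = normalize_gel_bands(self._table([[3, 1, 4, 1]]))
        twice = normalize_gel_bands(once)
        assert np.allclose(once.intensities, twice.intensities)

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=12).filter(lambda r: sum(r) > 0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_row_sums_to_one(self, row):
        out = normalize_gel_bands(self._table([row]))
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unit_max_option(self):
        out = normalize_gel_bands(self._table([[1, 4, 2, 0]]), mode="max")
        assert out.intensities.max() == pytest.approx(1.0)
        assert np.allclose(out.intensities[0], [0.25, 1.0, 0.5, 0.0])
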