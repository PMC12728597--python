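"""Yield, purity, peak resolution and pooling metrics from fitted mixtures.

Two yield definitions are exposed and labeled throughout:

* **measured yield** — spectrophotometer mass recovered in selected
  fractions divided by the input mass of target species.  This is the
  headline experimental quantity, and it counts *all* DNA mass in the
  fraction, so staple co-elution can push it above 1; values > 1 are
  reported with a warning flag, never clipped.
* **model yield** — the fitted target component's area captured inside an
  elution interval divided by its total area ``alpha``; a pure
  deconvolution-based quantity.

Purity is model-based only (fitted component AUC ratio): without
deconvolution a raw-data purity is unidentifiable, so none is offered.
Pooled purity over several fractions is computed on the union interval
as a single integral ratio (mass-weighted), not as a mean of per-fraction
purities.

Peak resolution uses the full-width-at-half-maximum definition
``Rs = 2 (t_R2 - t_R1) / (w1/2,1 + w1/2,2)`` with peak positions at the
fitted density maxima — note this keeps the factor 2 with FWHM widths,
not the pharmacopoeial 1.18 variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .mixture import LogNormalComponent, MixtureFit
from .profile_io import ColumnSpec, ElutionProfile, GelBandTable, fraction_interval

__all__ = [
    "component_mass_on_interval",
    "fraction_purity",
    "measured_yield",
    "peak_mode",
    "fwhm_numeric",
    "resolution",
    "resolution_from_peaks",
    "ResolutionResult",
    "pool_optimize",
    "FractionMetrics",
    "PoolMetrics",
    "PurityReport",
    "build_report",
    "aggregate_replicates",
    "ReplicateSummary",
    "normalize_gel_bands",
]


def component_mass_on_interval(component: LogNormalComponent, a: float, b: float) -> float:
    """Mass (ng) of one fitted component eluting between volumes ``a`` and ``b`` (μL).

    Computed as ``alpha * (F(b) - F(a))`` with F the log-normal CDF; the
    underlying normal CDF is evaluated by ``scipy.special.ndtr`` (absolute
    accuracy well below 1e-12).
    """
    if not (0 <= a < b):
        raise ValidationError(f"need 0 <= a < b, got a={a}, b={b}")
    return component.alpha * (float(component.cdf(b)) - float(component.cdf(a)))


def fraction_purity(fit: MixtureFit, a: float, b: float) -> float:
    """Target mass fraction on the elution interval (a, b): target AUC / total AUC.

    Raises :class:`UndefinedMetricError` when the interval carries
    essentially no mass of either component (below 1e-12 of the total).
    """
    m_target = component_mass_on_interval(fit.component_target, a, b)
    m_contam = component_mass_on_interval(fit.component_contaminant, a, b)
    total_alpha = fit.component_target.alpha + fit.component_contaminant.alpha
    if m_target + m_contam < 1e-12 * total_alpha:
        raise UndefinedMetricError(
            f"interval ({a}, {b}) μL carries no appreciable mass; purity undefined"
        )
    return m_target / (m_target + m_contam)


def measured_yield(
    profile: ElutionProfile,
    fractions: Iterable[int],
    column_spec: ColumnSpec,
) -> float:
    """Recovered mass in the selected fractions divided by the input mass.

    Counts all measured DNA mass (target + co-eluting contaminant), so the
    result may exceed 1; callers should surface the ``yield > 1`` case as a
    warning rather than an error.
    """
    if profile.input_mass_ng is None:
        raise ConfigurationError(
            f"replicate {profile.replicate_id!r} has no input_mass_ng; measured yield needs it"
        )
    fractions = sorted(set(int(f) for f in fractions))
    if not fractions:
        raise ValidationError("fraction selection must be nonempty")
    index = {int(f): i for i, f in enumerate(profile.fractions)}
    mass = 0.0
    for f in fractions:
        if f not in index:
            raise ValidationError(f"fraction {f} not present in replicate {profile.replicate_id!r}")
        mass += profile.concentrations[index[f]] * column_spec.fraction_volume_uL
    return mass / profile.input_mass_ng


def peak_mode(component: LogNormalComponent) -> float:
    """Elution volume (μL) at the component's density maximum: exp(mu - sigma^2)."""
    return component.mode_uL


def fwhm_numeric(component: LogNormalComponent) -> float:
    """Full width at half maximum (μL) of the component's density, by root finding.

    The two solutions of ``f(x) = f(mode)/2`` are located by bracketed
    root finding on either side of the mode; the bracket is grown or
    shrunk geometrically until the density falls below half maximum.
    Absolute tolerance 1e-9 μL.  The scaling ``alpha`` cancels in the
    half-max ratio, so the width is scale-free.
    """
    mode = component.mode_uL
    half = 0.5 * component.pdf(mode)

    def g(x: float) -> float:
        return component.pdf(x) - half

    # left bracket: shrink toward 0+ until below half-max
    lo = mode / 2.0
    while g(lo) > 0:
        lo /= 2.0
        if lo < 1e-300:  # pragma: no cover - unreachable for valid sigma
            raise ArithmeticError("left FWHM bracket failure")
    left = brentq(g, lo, mode, xtol=1e-10, rtol=8.9e-16)

    # right bracket: expand geometrically until below half-max
    hi = mode * 2.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e300:  # pragma: no cover
            raise ArithmeticError("right FWHM bracket failure")
    right = brentq(g, mode, hi, xtol=1e-10, rtol=8.9e-16)
    return right - left


@dataclass(frozen=True)
class ResolutionResult:
    """Peak-resolution bookkeeping for a two-component fit.

    ``t_r1 <= t_r2`` are the elution volumes at the two peak maxima (μL),
    ``w_half_i`` the corresponding full widths at half maximum (μL), and
    ``rs`` the dimensionless resolution; ``rs`` is zero exactly when the
    peaks coincide.
    """

    t_r1: float
    t_r2: float
    w_half_1: float
    w_half_2: float
    rs: float


def resolution_from_peaks(t_r1: float, t_r2: float, w_half_1: float, w_half_2: float) -> float:
    """The FWHM resolution formula on given peak positions and widths:
    ``Rs = 2 (t_R2 - t_R1) / (w1/2,1 + w1/2,2)``."""
    if w_half_1 <= 0 or w_half_2 <= 0:
        raise ValidationError("peak widths must be > 0")
    return 2.0 * (t_r2 - t_r1) / (w_half_1 + w_half_2)


def resolution(fit: MixtureFit) -> ResolutionResult:
    """Resolution of the two fitted peaks: ``Rs = 2 (t_R2 - t_R1) / (w1 + w2)``.

    Peak positions are the fitted density maxima and the widths come from
    :func:`fwhm_numeric`; components are ordered so ``t_r1 <= t_r2``.
    Raises :class:`UndefinedMetricError` when a component has zero mass
    (a single-species profile has no pairwise resolution).
    """
    c1, c2 = fit.component_target, fit.component_contaminant
    if c1.alpha <= 0 or c2.alpha <= 0:
        raise UndefinedMetricError("resolution undefined when a component has alpha = 0")
    t1, t2 = peak_mode(c1), peak_mode(c2)
    w1, w2 = fwhm_numeric(c1), fwhm_numeric(c2)
    if t1 > t2:
        t1, t2 = t2, t1
        w1, w2 = w2, w1
    rs = resolution_from_peaks(t1, t2, w1, w2)
    return ResolutionResult(t_r1=t1, t_r2=t2, w_half_1=w1, w_half_2=w2, rs=rs)


def _interval_metrics(fit: MixtureFit, a: float, b: float) -> tuple[float, float]:
    """(model purity, model yield) on an elution interval."""
    m_t = component_mass_on_interval(fit.component_target, a, b)
    m_c = component_mass_on_interval(fit.component_contaminant, a, b)
    alpha_t = fit.component_target.alpha
    purity = m_t / (m_t + m_c) if (m_t + m_c) > 0 else math.nan
    model_yield = m_t / alpha_t if alpha_t > 0 else math.nan
    return purity, model_yield


def pool_optimize(
    fit: MixtureFit,
    column_spec: ColumnSpec,
    min_purity: float,
) -> tuple[int, ...]:
    """Best contiguous fraction pool: maximal model yield at ``purity >= min_purity``.

    Exhaustive search over all O(N²) contiguous fraction intervals —
    exact at collection-scale N.  Ties are broken by fewer fractions,
    then by earlier start.  Returns an empty tuple when no interval
    reaches the purity floor.
    """
    if not (0 < min_purity <= 1) and min_purity != 0:
        raise ConfigurationError("min_purity must lie in (0, 1] (0 allowed as 'no constraint')")
    n = column_spec.n_fractions
    best: tuple[float, int, int, tuple[int, ...]] | None = None  # (yield, -len, -start, pool)
    for start in range(1, n + 1):
        for end in range(start, n + 1):
            a = fraction_interval(start, column_spec)[0]
            b = fraction_interval(end, column_spec)[1]
            try:
                purity = fraction_purity(fit, max(a, 0.0), b)
            except UndefinedMetricError:
                continue
            if purity + 1e-15 < min_purity:
                continue
            _, model_yield = _interval_metrics(fit, max(a, 1e-12), b)
            key = (model_yield, -(end - start + 1), -start)
            if best is None or key > best[:3]:
                best = (model_yield, -(end - start + 1), -start, tuple(range(start, end + 1)))
    return best[3] if best is not None else ()


@dataclass(frozen=True)
class FractionMetrics:
    index: int
    volume_uL: float
    mass_ng: float
    measured_yield: float | None
    model_purity: float
    model_yield: float


@dataclass(frozen=True)
class PoolMetrics:
    fractions: tuple[int, ...]
    mass_ng: float
    measured_yield: float | None
    model_purity: float
    model_yield: float
    yield_exceeds_one: bool = False


@dataclass(frozen=True)
class PurityReport:
    """Per-fraction and pooled metrics for one fitted replicate."""

    replicate_id: str
    fit: MixtureFit
    fractions: tuple[FractionMetrics, ...]
    pooled: PoolMetrics
    resolution: ResolutionResult


def build_report(
    profile: ElutionProfile,
    fit: MixtureFit,
    column_spec: ColumnSpec,
    pool_fractions: Sequence[int],
) -> PurityReport:
    """Assemble the per-fraction and pooled metrics for one replicate.

    ``pool_fractions`` are the fractions whose union elution interval forms
    the pooled result (e.g. the recommendation from :func:`pool_optimize`,
    or a manual choice such as the two peak fractions).
    """
    per_fraction: list[FractionMetrics] = []
    for f, v, c in zip(profile.fractions, profile.volumes_uL, profile.concentrations):
        a, b = fraction_interval(int(f), column_spec)
        purity, model_yield = _interval_metrics(fit, max(a, 1e-12), b)
        mass = float(c) * column_spec.fraction_volume_uL
        myield = (
            mass / profile.input_mass_ng if profile.input_mass_ng is not None else None
        )
        per_fraction.append(
            FractionMetrics(
                index=int(f),
                volume_uL=float(v),
                mass_ng=mass,
                measured_yield=myield,
                model_purity=purity,
                model_yield=model_yield,
            )
        )

    pool = tuple(sorted(set(int(f) for f in pool_fractions)))
    if pool:
        if any(np.diff(pool) != 1):
            raise ValidationError("pooled fractions must be contiguous")
        a = fraction_interval(pool[0], column_spec)[0]
        b = fraction_interval(pool[-1], column_spec)[1]
        purity, model_yield = _interval_metrics(fit, max(a, 1e-12), b)
        mass = sum(fm.mass_ng for fm in per_fraction if fm.index in pool)
        myield = (
            measured_yield(profile, pool, column_spec)
            if profile.input_mass_ng is not None
            else None
        )
        pooled = PoolMetrics(
            fractions=pool,
            mass_ng=mass,
            measured_yield=myield,
            model_purity=purity,
            model_yield=model_yield,
            yield_exceeds_one=bool(myield is not None and myield > 1),
        )
    else:
        pooled = PoolMetrics(
            fractions=(), mass_ng=0.0, measured_yield=None,
            model_purity=math.nan, model_yield=0.0,
        )

    return PurityReport(
        replicate_id=profile.replicate_id,
        fit=fit,
        fractions=tuple(per_fraction),
        pooled=pooled,
        resolution=resolution(fit),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate mean ± sample SD of every metric.

    ``per_fraction`` maps fraction index -> {metric: (mean, sd)};
    ``pooled`` and ``resolution`` map metric -> (mean, sd).  Sample SD
    uses the n−1 denominator and is reported as 0 for a single replicate.
    """

    n_replicates: int
    per_fraction: Mapping[int, Mapping[str, tuple[float, float]]]
    pooled: Mapping[str, tuple[float, float]]
    resolution: Mapping[str, tuple[float, float]]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 1 or np.all(arr == arr[0]):
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def aggregate_replicates(reports: Sequence[PurityReport]) -> ReplicateSummary:
    """Mean and sample SD of every metric across replicate reports.

    All reports must cover the same fraction indices and the same pooled
    fraction set.
    """
    if not reports:
        raise ValidationError("need at least one report")
    base_fracs = tuple(fm.index for fm in reports[0].fractions)
    base_pool = reports[0].pooled.fractions
    for r in reports[1:]:
        if tuple(fm.index for fm in r.fractions) != base_fracs:
            raise ValidationError("replicate reports have mismatched fraction sets")
        if r.pooled.fractions != base_pool:
            raise ValidationError("replicate reports have mismatched pooled fraction sets")

    frac_metrics = ("mass_ng", "measured_yield", "model_purity", "model_yield")
    per_fraction: dict[int, dict[str, tuple[float, float]]] = {}
    for i, idx in enumerate(base_fracs):
        entry: dict[str, tuple[float, float]] = {}
        for m in frac_metrics:
            vals = [getattr(r.fractions[i], m) for r in reports]
            if any(v is None for v in vals):
                continue
            entry[m] = _mean_sd(vals)
        per_fraction[idx] = entry

    pooled: dict[str, tuple[float, float]] = {}
    for m in frac_metrics:
        vals = [getattr(r.pooled, m) for r in reports]
        if any(v is None for v in vals):
            continue
        pooled[m] = _mean_sd(vals)

    res: dict[str, tuple[float, float]] = {}
    for m in ("t_r1", "t_r2", "w_half_1", "w_half_2", "rs"):
        res[m] = _mean_sd([getattr(r.resolution, m) for r in reports])

    return ReplicateSummary(
        n_replicates=len(reports),
        per_fraction=per_fraction,
        pooled=pooled,
        resolution=res,
    )


def normalize_gel_bands(
    table: GelBandTable, mode: Literal["sum", "max"] = "sum"
) -> GelBandTable:
    """Normalize each species' band-intensity row to 1.

    ``sum`` (default) divides each row by its total so intensities read as
    the species' fractional distribution across fractions; ``max`` divides
    by the row maximum instead (peak normalized to 1).  Idempotent in
    either mode.  All-zero rows are rejected at table construction.
    """
    if mode not in ("sum", "max"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    denom = table.intensities.sum(axis=1) if mode == "sum" else table.intensities.max(axis=1)
    return GelBandTable(
        species=table.species,
        fractions=table.fractions,
        intensities=table.intensities / denom[:, None],
    )
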