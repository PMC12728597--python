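"""Two-component log-normal elution model and its least-squares fit.

The elution profile of a size-exclusion purification of DNA origami is
modeled as the sum of two scaled log-normal densities in elution volume x:

    y(x) = a1/(x s1 sqrt(2 pi)) exp(-(ln x - m1)^2 / (2 s1^2))
         + a2/(x s2 sqrt(2 pi)) exp(-(ln x - m2)^2 / (2 s2^2))

where y is the fraction concentration (ng/μL), m (``mu``) is the mean of
the log elution volume, s (``sigma``) its standard deviation, and the
positive scaling constants a (``alpha``) carry units of mass (ng), since
concentration integrated over volume is mass.  ``log`` is the natural
logarithm throughout.  The earlier-eluting (smaller-mode) component is
the large species — the nanostructures — and the later one the excess
staples; this identification is configurable for non-SEC uses.

Fitting is bounded nonlinear least squares with a deterministic
multi-start initialization, so identical input and options always give
the identical fit with no random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .errors import ConfigurationError, InsufficientDataError, NonConvergenceError, ValidationError
from .profile_io import ElutionProfile

__all__ = [
    "LogNormalComponent",
    "MixtureFit",
    "FitOptions",
    "mixture_value",
    "initialize_params",
    "fit_mixture",
    "mean_profile",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class LogNormalComponent:
    """One elution peak: a log-normal density scaled by a mass ``alpha``.

    ``mu`` is the mean of ln(elution volume/μL) (dimensionless), ``sigma``
    its standard deviation (> 0) and ``alpha`` the component's total mass
    in ng (the integral of the scaled density over all volumes).
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")

    @classmethod
    def from_mode(cls, mode_uL: float, sigma: float, alpha: float) -> "LogNormalComponent":
        """Build a component from its peak position (mode of the density, μL)."""
        if not mode_uL > 0:
            raise ValidationError("mode must be > 0")
        return cls(mu=math.log(mode_uL) + sigma**2, sigma=sigma, alpha=alpha)

    @property
    def mode_uL(self) -> float:
        """Elution volume at the density maximum: exp(mu - sigma^2)."""
        return math.exp(self.mu - self.sigma**2)

    def pdf(self, x) -> np.ndarray | float:
        """Unscaled log-normal density at elution volume ``x`` (> 0)."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValidationError("elution volume must be > 0")
        z = (np.log(x) - self.mu) / self.sigma
        out = np.exp(-0.5 * z * z) / (x * self.sigma * _SQRT2PI)
        return out if out.ndim else float(out)

    def value(self, x) -> np.ndarray | float:
        """Scaled density alpha * pdf(x): the component's concentration contribution."""
        out = self.alpha * np.asarray(self.pdf(x))
        return out if out.ndim else float(out)

    def cdf(self, x) -> np.ndarray | float:
        """Log-normal CDF Phi((ln x - mu)/sigma); 0 for x <= 0."""
        x = np.asarray(x, dtype=float)
        out = np.where(x > 0, ndtr((np.log(np.where(x > 0, x, 1.0)) - self.mu) / self.sigma), 0.0)
        return out if out.ndim else float(out)


def mixture_value(component1: LogNormalComponent, component2: LogNormalComponent, x):
    """Model concentration (ng/μL) at elution volume ``x`` (μL): sum of both scaled densities."""
    return component1.value(x) + component2.value(x)


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_mixture`.

    Bounds default to sigma in [1e-3, 2], mu within one log-unit of the
    observed volume range, and alpha in [0, 10 × total measured mass].
    Tolerances apply to parameter and cost change (``xtol``/``ftol``).
    """

    sigma_bounds: tuple[float, float] = (1e-3, 2.0)
    mu_bounds: tuple[float, float] | None = None  # None: derive from data
    alpha_bounds: tuple[float, float] | None = None  # None: derive from data
    tol: float = 1e-10
    max_iter: int = 1000
    target_is_smaller_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma_bounds", "mu_bounds", "alpha_bounds"):
            b = getattr(self, name)
            if b is not None and not b[0] < b[1]:
                raise ConfigurationError(f"{name} must satisfy lower < upper")
        if self.sigma_bounds[0] <= 0:
            raise ConfigurationError("sigma lower bound must be > 0")


@dataclass(frozen=True)
class MixtureFit:
    """Result of fitting the two-component model to one profile.

    ``component_target`` is the earlier-eluting peak (the nanostructures
    under the default size-exclusion identification), ``component_contaminant``
    the later one (staples).  ``rss`` is the residual sum of squares in
    (ng/μL)², ``r_squared`` the usual coefficient of determination, and
    ``poorly_identified`` flags a tie in peak position.
    """

    component_target: LogNormalComponent
    component_contaminant: LogNormalComponent
    rss: float
    r_squared: float
    converged: bool
    n_points: int
    poorly_identified: bool = False

    @property
    def components(self) -> tuple[LogNormalComponent, LogNormalComponent]:
        return (self.component_target, self.component_contaminant)

    def value(self, x):
        return mixture_value(self.component_target, self.component_contaminant, x)


def _weighted_log_moments(vol: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Mass-weighted mean and SD of log volume; SD floored for degenerate sides."""
    w = np.maximum(w, 0.0)
    if w.sum() <= 0:
        return float(np.mean(np.log(vol))), 0.3
    lv = np.log(vol)
    mu = float(np.average(lv, weights=w))
    var = float(np.average((lv - mu) ** 2, weights=w))
    sigma = math.sqrt(max(var, 1e-4))
    return mu, sigma


def initialize_params(profile: ElutionProfile) -> list[np.ndarray]:
    """Deterministic multi-start candidates ``[mu1, s1, a1, mu2, s2, a2]``.

    Two families of starts:

    * quantile splits — the mass-weighted volume distribution is split at
      the 0.3/0.4/0.5/0.6/0.7 quantiles and per-side log-moment estimates
      of (mu, sigma) with trapezoid-AUC estimates of alpha seed each side;
    * local-maxima seeding — when the observed profile has two or more
      interior local maxima, the two tallest seed the component positions.

    Raises :class:`InsufficientDataError` for < 5 points or < 2 nonzero
    concentrations.
    """
    vol = profile.volumes_uL
    conc = profile.concentrations
    if profile.n_points < 5 or np.count_nonzero(conc) < 2:
        raise InsufficientDataError(
            "need >= 5 points with >= 2 nonzero concentrations to initialize the fit"
        )

    total_auc = float(np.trapezoid(conc, vol))
    if total_auc <= 0:
        total_auc = float(np.sum(conc) * np.mean(np.diff(vol)))
    # weights for the empirical mass-weighted volume distribution
    w = np.maximum(conc, 0.0)
    cum = np.cumsum(w)
    cum = cum / cum[-1]

    candidates: list[np.ndarray] = []
    for q in (0.3, 0.4, 0.5, 0.6, 0.7):
        k = int(np.searchsorted(cum, q, side="left")) + 1
        k = min(max(k, 1), profile.n_points - 1)
        lo, hi = slice(0, k), slice(k, None)
        mu1, s1 = _weighted_log_moments(vol[lo], w[lo])
        mu2, s2 = _weighted_log_moments(vol[hi], w[hi])
        a1 = float(np.trapezoid(conc[lo], vol[lo])) if k > 1 else float(w[0] * np.mean(np.diff(vol)))
        a2 = float(np.trapezoid(conc[hi], vol[hi])) if profile.n_points - k > 1 else float(
            w[-1] * np.mean(np.diff(vol))
        )
        rest = max(total_auc - a1 - a2, 0.0)
        a1 += rest / 2
        a2 += rest / 2
        candidates.append(np.array([mu1, _clip_sigma(s1), max(a1, 1e-12),
                                    mu2, _clip_sigma(s2), max(a2, 1e-12)]))

    # single-component-like starts: all mass in one peak, a vanishing second
    mu_all, s_all = _weighted_log_moments(vol, w)
    for mu2 in (mu_all + 0.5, mu_all - 0.5):
        candidates.append(np.array([mu_all, _clip_sigma(s_all), total_auc,
                                    mu2, 0.3, 1e-6 * max(total_auc, 1.0)]))

    # local-maxima seeding
    interior = np.flatnonzero(
        (conc[1:-1] >= conc[:-2]) & (conc[1:-1] >= conc[2:]) & (conc[1:-1] > 0)
    ) + 1
    if interior.size >= 2:
        top2 = interior[np.argsort(conc[interior])[::-1][:2]]
        i, j = sorted(top2)
        s0 = 0.2
        for split in (True,):
            a1 = total_auc * conc[i] / (conc[i] + conc[j])
            a2 = total_auc - a1
            candidates.append(np.array([
                math.log(vol[i]) + s0**2, s0, max(a1, 1e-12),
                math.log(vol[j]) + s0**2, s0, max(a2, 1e-12),
            ]))
    return candidates


def _clip_sigma(s: float, lo: float = 1e-3, hi: float = 2.0) -> float:
    return float(min(max(s, max(lo, 0.02)), hi))


def _resolve_bounds(profile: ElutionProfile, options: FitOptions,
                    fraction_volume_uL: float | None) -> tuple[np.ndarray, np.ndarray]:
    vol = profile.volumes_uL
    if options.mu_bounds is not None:
        mu_lo, mu_hi = options.mu_bounds
    else:
        mu_lo, mu_hi = math.log(vol.min()) - 1.0, math.log(vol.max()) + 1.0
    if options.alpha_bounds is not None:
        a_lo, a_hi = options.alpha_bounds
    else:
        dv = fraction_volume_uL if fraction_volume_uL is not None else float(np.mean(np.diff(vol)))
        total_mass = float(np.sum(profile.concentrations) * dv)
        a_lo, a_hi = 0.0, 10.0 * max(total_mass, 1e-9)
    s_lo, s_hi = options.sigma_bounds
    lower = np.array([mu_lo, s_lo, a_lo, mu_lo, s_lo, a_lo])
    upper = np.array([mu_hi, s_hi, a_hi, mu_hi, s_hi, a_hi])
    return lower, upper


def _order_components(c1: LogNormalComponent, c2: LogNormalComponent,
                      target_is_smaller_mode: bool) -> tuple[LogNormalComponent, LogNormalComponent, bool]:
    """Canonical ordering: target = smaller mode; ties broken by smaller sigma and flagged."""
    m1, m2 = c1.mode_uL, c2.mode_uL
    tie = math.isclose(m1, m2, rel_tol=1e-9)
    if tie:
        first, second = (c1, c2) if c1.sigma <= c2.sigma else (c2, c1)
        return first, second, True
    first, second = (c1, c2) if m1 < m2 else (c2, c1)
    if not target_is_smaller_mode:
        first, second = second, first
    return first, second, False


def fit_mixture(
    profile: ElutionProfile,
    options: FitOptions | None = None,
    fraction_volume_uL: float | None = None,
    weights: np.ndarray | None = None,
) -> MixtureFit:
    """Fit the two-log-normal model to a profile by bounded least squares.

    All candidates from :func:`initialize_params` are run through
    ``scipy.optimize.least_squares`` (Trust Region Reflective, analytic
    bounds) and the converged solution with the lowest residual sum of
    squares is returned, components ordered so the target has the smaller
    mode.  Deterministic given identical input and options.

    ``weights``, when given, multiply the residuals (used by pooled
    inverse-variance fitting).  Raises :class:`NonConvergenceError`
    carrying the best non-converged solution if no start converges.
    """
    options = options or FitOptions()
    starts = initialize_params(profile)
    lower, upper = _resolve_bounds(profile, options, fraction_volume_uL)

    vol = profile.volumes_uL
    conc = profile.concentrations
    w = np.ones_like(conc) if weights is None else np.asarray(weights, dtype=float)

    log_vol = np.log(vol)

    def residuals(p: np.ndarray) -> np.ndarray:
        mu1, s1, a1, mu2, s2, a2 = p
        z1 = (log_vol - mu1) / s1
        z2 = (log_vol - mu2) / s2
        model = (a1 / (vol * s1 * _SQRT2PI)) * np.exp(-0.5 * z1 * z1) + (
            a2 / (vol * s2 * _SQRT2PI)
        ) * np.exp(-0.5 * z2 * z2)
        return w * (model - conc)

    best: tuple[float, np.ndarray, bool] | None = None  # (rss, params, converged)
    for start in starts:
        p0 = np.clip(start, lower + 1e-12, upper - 1e-12)
        res = least_squares(
            residuals,
            p0,
            bounds=(lower, upper),
            method="trf",
            xtol=options.tol,
            ftol=options.tol,
            gtol=None,
            max_nfev=options.max_iter * p0.size,
        )
        rss = float(2.0 * res.cost)
        converged = bool(res.success)
        if best is None or (converged, -rss) > (best[2], -best[0]):
            best = (rss, res.x, converged)

    assert best is not None
    _, params, converged = best
    c_first = LogNormalComponent(mu=float(params[0]), sigma=float(params[1]), alpha=float(params[2]))
    c_second = LogNormalComponent(mu=float(params[3]), sigma=float(params[4]), alpha=float(params[5]))
    target, contaminant, tie = _order_components(c_first, c_second, options.target_is_smaller_mode)

    # report rss/r^2 on the plain (unweighted) residuals of the final model
    model = mixture_value(c_first, c_second, vol)
    rss = float(np.sum((np.asarray(model) - conc) ** 2))
    tss = float(np.sum((conc - conc.mean()) ** 2))
    # guard: flat observed profile
    r_squared = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)

    fit = MixtureFit(
        component_target=target,
        component_contaminant=contaminant,
        rss=rss,
        r_squared=r_squared,
        converged=converged,
        n_points=profile.n_points,
        poorly_identified=tie,
    )
    if not converged:
        raise NonConvergenceError(
            f"no optimizer start converged for replicate {profile.replicate_id!r} "
            f"(best rss {rss:.3g})",
            best_fit=fit,
        )
    return fit


def mean_profile(profiles: list[ElutionProfile]) -> tuple[ElutionProfile, np.ndarray]:
    """Across-replicate mean profile and per-fraction standard deviations.

    All profiles must share the same fraction grid.  The returned SDs
    (sample SD, n−1; zeros for a single replicate) support
    inverse-variance weighting in pooled fits.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    base = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.fractions, base.fractions) or not np.allclose(
            p.volumes_uL, base.volumes_uL
        ):
            raise ValidationError("profiles must share an identical fraction grid to pool")
    conc = np.vstack([p.concentrations for p in profiles])
    mean = conc.mean(axis=0)
    sd = conc.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    pooled = ElutionProfile(
        replicate_id="pooled-mean",
        fractions=base.fractions,
        volumes_uL=base.volumes_uL,
        concentrations=mean,
        input_mass_ng=base.input_mass_ng,
    )
    return pooled, sd
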