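"""Exception hierarchy for gsecquant.

All package errors derive from :class:`GsecQuantError` so callers can catch
everything from this package with one clause while still distinguishing
I/O-format problems, invalid data, configuration mistakes and numerical
failures.
"""


class GsecQuantError(Exception):
    """Base class for all gsecquant errors."""


class FormatError(GsecQuantError):
    """An input file does not have the expected structure (e.g. a missing column)."""


class ValidationError(GsecQuantError):
    """Input data violates an invariant (negative concentration, duplicate row, ...)."""


class ConfigurationError(GsecQuantError):
    """Options or metadata required for a computation are missing or inconsistent."""


class InsufficientDataError(GsecQuantError):
    """A profile has too few usable points to fit the two-component model."""


class NonConvergenceError(GsecQuantError):
    """No optimizer start converged.

    Carries the best non-converged fit so the caller can inspect it.
    """

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class UndefinedMetricError(GsecQuantError):
    """A metric is mathematically undefined for the given input
    (e.g. purity on an interval carrying essentially no mass)."""
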