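"""Exception hierarchy shared across the package.

All domain errors derive from :class:`ThermoperfError` so callers can catch
one base class at pipeline boundaries.  Validation problems (bad input
files, schema mismatches) raise :class:`ValidationError`; computational
failures (undefined criteria, failed selection) raise the more specific
subclasses.
"""

from __future__ import annotations


class ThermoperfError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermoperfError):
    """Input data violates a schema or a documented precondition."""


class MissingDataError(ThermoperfError):
    """A required field (e.g. a tolerance mean) is absent."""


class InvalidMetricsError(ThermoperfError):
    """Derived thermal metrics are inconsistent (e.g. optimum above CTmax)."""


class UndefinedAICcError(ThermoperfError):
    """AICc requested with n <= k + 1, where the correction term blows up."""


class SelectionError(ThermoperfError):
    """No candidate curve passed the R-squared floor."""

    def __init__(self, message: str, best_r2: float | None = None):
        super().__init__(message)
        self.best_r2 = best_r2


class AmbiguousCurveError(ThermoperfError):
    """Clamped curve has more than one local maximum above the breadth level."""


class InvalidFrameCountError(ThermoperfError):
    """Video frame count is non-positive or fractional."""


class ComputationError(ThermoperfError):
    """A numeric routine failed (non-convergence, degenerate inputs)."""
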