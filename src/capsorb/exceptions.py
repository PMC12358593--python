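"""Exception hierarchy.

All capsorb errors derive from :class:`CapsorbError` so callers can catch
the package's failures with a single except clause; each subclass also
derives from the closest builtin (ValueError/RuntimeError) so untyped
call sites behave sensibly.
"""


class CapsorbError(Exception):
    """Base class for all capsorb errors."""


class DomainError(CapsorbError, ValueError):
    """An input lies outside a model's mathematical domain (e.g. aw >= 1/k for GAB)."""


class RangeError(CapsorbError, ValueError):
    """A requested output value is unattainable; carries the attainable interval.

    Attributes
    ----------
    attainable : tuple[float, float] | None
        The (low, high) interval of values the model can reach, when known.
    """

    def __init__(self, message: str, attainable: "tuple[float, float] | None" = None):
        super().__init__(message)
        self.attainable = attainable


class ValidationError(CapsorbError, ValueError):
    """A record or configuration violates its invariants."""


class UnsupportedModelError(CapsorbError, ValueError):
    """An operation was requested for a model it does not apply to."""


class DegenerateDataError(CapsorbError, ValueError):
    """Data without the variance the computation requires (e.g. zero TSS)."""


class ConvergenceError(CapsorbError, RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: "list | None" = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
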