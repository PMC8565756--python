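"""Exception and warning hierarchy for the cndc package."""


class CndcError(Exception):
    """Base class for all cndc errors."""


class FormatError(CndcError):
    """A delimited input file does not match the expected layout."""


class ValidationError(CndcError):
    """Input rows or configuration fields violate a documented invariant.

    ``details`` carries row-indexed (or field-named) diagnostics.
    """

    def __init__(self, message, details=None):
        self.details = list(details or [])
        if self.details:
            shown = "; ".join(self.details[:5])
            if len(self.details) > 5:
                shown += f"; ... ({len(self.details) - 5} more)"
            message = f"{message}: {shown}"
        super().__init__(message)


class InsufficientDataError(CndcError):
    """Too few observations/points for the requested operation."""


class DegenerateFitError(CndcError):
    """A regression design is rank deficient (e.g. zero predictor variance)."""


class UnusableDateError(CndcError):
    """Skip signal: a sampling date lacks the limited/non-limited contrast
    needed to extract a critical point."""


class CndcWarning(UserWarning):
    """Base class for cndc warnings."""


class ObliqueSlopeWarning(CndcWarning):
    """The oblique line through N-limited treatments has non-positive slope."""


class ExtrapolationWarning(CndcWarning):
    """A curve is evaluated, or a point extracted, outside the data range."""
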