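"""Exception hierarchy.

All naagif-specific errors derive from :class:`NaagifError` so callers can
catch the package's failures with a single except clause; the concrete
subclasses mirror the failure modes of the pipeline stages (bad parameters,
bad files, numerical breakdown, fit failure).
"""


class NaagifError(Exception):
    """Base class for all naagif errors."""


class InvalidParameterError(NaagifError, ValueError):
    """A physical or structural parameter violates its admissible range."""


class RangeError(NaagifError, ValueError):
    """A wavelength window or grid lies outside the supported range."""


class StructuralError(NaagifError, ValueError):
    """Inconsistent array shapes or misaligned wavelength grids."""


class DegenerateSpectrumError(NaagifError, ValueError):
    """A spectrum is unusable for the requested metric (e.g. zero reference peak)."""


class NumericalFailureError(NaagifError, RuntimeError):
    """A numerical routine found no admissible solution."""


class FitError(NaagifError, RuntimeError):
    """Nonlinear least squares failed to converge."""


class InsufficientDataError(NaagifError, ValueError):
    """Too few data points for the requested operation."""


class ConfigError(NaagifError, ValueError):
    """Malformed or incomplete configuration."""


class ParseError(NaagifError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
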