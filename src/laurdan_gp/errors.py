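"""Exception hierarchy for the Laurdan-GP pipeline.

Every stage raises a subclass of :class:`LaurdanError`, so callers (and the
CLI) can fail with a stage-specific message instead of a bare ValueError.
"""


class LaurdanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LaurdanError):
    """Input file does not conform to the expected dialect (missing column,
    unparseable value, duplicated row)."""


class SpectrumValidationError(LaurdanError):
    """A spectrum violates its invariants (negative intensity, non-increasing
    wavelength grid, length mismatch)."""


class GridMismatchError(LaurdanError):
    """Two spectra or curves that must share a grid do not. No interpolation
    is ever performed; a mismatched grid is a hard error."""


class MissingChannelError(LaurdanError):
    """A requested channel wavelength is not a point of the spectrum grid."""


class DegenerateSpectrumError(LaurdanError):
    """Both channel intensities are zero; GP is undefined."""


class InsufficientPointsError(LaurdanError):
    """Too few points for the requested operation (e.g. a central difference
    needs at least three temperatures)."""


class NoTransitionError(LaurdanError):
    """The derivative curve carries no detectable transition peak."""


class TruncatedPeakError(LaurdanError):
    """The derivative peak does not fall below half maximum on both sides
    inside the measured range, so a width cannot be reported."""


class UnknownPresetError(LaurdanError):
    """Requested a synthetic preset that does not exist."""
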