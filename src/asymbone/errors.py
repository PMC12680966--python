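"""Exception hierarchy for the asymbone pipeline.

Every stage raises a subclass of :class:`AsymboneError` so callers can
distinguish pipeline failures from programming errors.
"""


class AsymboneError(Exception):
    """Base class for all asymbone errors."""


class ParameterError(AsymboneError, ValueError):
    """Invalid user-supplied parameter (window bounds, counts, exponents...)."""


class GenerationError(AsymboneError):
    """Synthetic geometry could not be generated (self-intersection, enclosure)."""


class AlignmentError(AsymboneError):
    """Bone could not be aligned (degenerate geometry, zero extent)."""


class ConfigurationError(AsymboneError):
    """Inconsistent sectioning configuration (levels inside the excluded band)."""


class SectioningError(AsymboneError):
    """A cutting plane produced no usable closed contour."""


class SolidSectionError(SectioningError):
    """The section has no interior (endosteal) curve."""


class NonStarShapeError(SectioningError):
    """A ray from the section centre crosses a contour more than once."""

    def __init__(self, message, level_percent=None, angle_deg=None):
        super().__init__(message)
        self.level_percent = level_percent
        self.angle_deg = angle_deg


class AggregationError(AsymboneError):
    """One or more sections of a specimen failed; carries the failed levels."""

    def __init__(self, message, failed_levels=()):
        super().__init__(message)
        self.failed_levels = list(failed_levels)


class InputError(AsymboneError, ValueError):
    """Mismatched or malformed analysis input (landmark counts, dimensions)."""


class ConvergenceError(AsymboneError):
    """Iterative superimposition did not converge within the iteration cap."""


class InferenceError(AsymboneError):
    """A statistical routine received groups too small to analyse."""


class MapError(AsymboneError):
    """Degenerate geometry in a per-landmark map (zero neighbour distance)."""
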