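"""Exception hierarchy for the quantification pipeline.

All errors derive from :class:`PetQuantError`; argument-validation errors
additionally derive from :class:`ValueError` so callers may catch either.
"""


class PetQuantError(Exception):
    """Base class for every error raised by this package."""


class InvalidArgumentError(PetQuantError, ValueError):
    """A precondition on an operation's arguments was violated."""


class GeometryError(PetQuantError):
    """Phantom geometry is inconsistent (overlapping spheres, out-of-grid)."""


class SegmentationError(PetQuantError):
    """Threshold delineation could not produce a valid mask."""


class CalibrationError(PetQuantError):
    """Optimal-threshold search failed for every candidate threshold."""


class ConfigurationError(PetQuantError):
    """Run configuration is inconsistent or incomplete."""


class FormatError(PetQuantError):
    """An input file could not be interpreted (bad NIfTI/DICOM geometry or
    missing rescale metadata); the message names the offending attribute."""


class DegenerateTestError(PetQuantError):
    """A statistical test was requested on degenerate data (e.g. all paired
    differences are exactly zero)."""
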