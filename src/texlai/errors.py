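"""Exception hierarchy.

All package errors derive from :class:`TexlaiError` so callers can catch one
type at the pipeline boundary while tests discriminate the specific failure.
"""


class TexlaiError(Exception):
    """Base class for all errors raised by texlai."""


class DomainError(TexlaiError):
    """A mathematically undefined operation (zero denominator, zero variance)."""


class MissingBandError(TexlaiError, KeyError):
    """A required spectral band is absent from the input."""

    def __init__(self, wavelength: int):
        self.wavelength = wavelength
        super().__init__(f"required band at {wavelength} nm not present")


class EmptyROIError(TexlaiError):
    """A region of interest selects no usable pixels."""


class StackFormatError(TexlaiError):
    """Raster content disagrees with the declared band registry."""
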