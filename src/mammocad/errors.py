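"""Exception hierarchy shared across the toolkit."""


class MammocadError(Exception):
    """Base class for all mammocad errors."""


class InputFormatError(MammocadError):
    """File could not be read as any supported image format."""


class MissingPixelDataError(InputFormatError):
    """DICOM file carries no pixel data."""


class UnsupportedFormatError(MammocadError):
    """Requested output format cannot represent the image losslessly."""


class ParameterError(MammocadError, ValueError):
    """An operation parameter is out of its valid range."""


class DegenerateInputError(MammocadError):
    """Input has no usable structure (e.g. constant image for histogram init)."""


class MissingSpacingError(MammocadError):
    """A physical (mm) quantity was requested but the image has no pixel spacing."""


class BoundsError(MammocadError, IndexError):
    """A pixel coordinate lies outside the image."""


class DimensionError(MammocadError):
    """Array shapes are inconsistent."""


class ConfigurationError(MammocadError):
    """A configuration object is internally inconsistent or incompatible with the data."""


class PhantomSpecError(MammocadError):
    """A synthetic-phantom specification is invalid (e.g. lesion out of bounds)."""


class WriteError(MammocadError, OSError):
    """Filesystem-level failure while writing an artifact."""


class UnsupportedTemplateError(MammocadError):
    """A DICOM-SR document does not follow the report layout this package writes."""
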