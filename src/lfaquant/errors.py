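"""Exception hierarchy for the lfaquant pipeline.

Errors are grouped so the CLI can map them onto exit codes: usage/config
mistakes versus data/processing failures.
"""


class LfaQuantError(Exception):
    """Base class for all lfaquant errors."""


class UsageError(LfaQuantError):
    """Caller passed parameters outside the documented contract."""


class ImageReadError(LfaQuantError):
    """A file could not be read as a raster image."""


class ImageFormatError(LfaQuantError):
    """Image exists but its format (bit depth, layout) is unsupported."""


class GeometryError(LfaQuantError):
    """A crop region or window falls outside the image it addresses."""


class DegenerateInputError(LfaQuantError):
    """An operation received input with no usable structure (e.g. all
    pixel values identical for Otsu thresholding)."""


class DetectionError(LfaQuantError):
    """Fewer bands were found than the caller expected."""


class SchemaError(LfaQuantError):
    """A CSV table is missing a mandatory column."""


class TableParseError(LfaQuantError):
    """A CSV cell could not be parsed; carries the 1-based file line."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class IntegrityError(LfaQuantError):
    """Join keys are duplicated or otherwise inconsistent."""


class InsufficientDataError(LfaQuantError):
    """Too few points/replicates for the requested statistic."""


class DegenerateDesignError(LfaQuantError):
    """Calibration design has no concentration variance."""


class DegenerateFitError(LfaQuantError):
    """Calibration fit cannot be inverted (zero slope)."""


class PixelRangeError(LfaQuantError):
    """Synthetic signal exceeded the representable pixel range with
    saturation clipping disabled."""
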