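"""Exception hierarchy for the conversion pipeline.

Exit-code mapping used by the command-line entry point:

* 2 — usage errors (bad invocation, unreadable required input)
* 3 — input format errors (malformed tck / NIfTI / DICOM content)
* 4 — geometry errors (undecomposable affines, unmatched label grids)
"""


class ConversionError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class UsageError(ConversionError):
    """The tool was invoked incorrectly (missing/unreadable inputs)."""

    exit_code = 2


class FormatError(ConversionError):
    """An input file does not conform to its declared format."""

    exit_code = 3


class UnsupportedEncodingError(FormatError):
    """A tck file declares a coordinate encoding this reader does not accept."""


class CorruptFileError(FormatError):
    """A file is structurally valid up to a point, then inconsistent."""


class InvalidInputError(FormatError):
    """In-memory input violates a documented precondition (non-finite
    coordinates, non-integer labels, empty frames...)."""


class UnsupportedInputError(FormatError):
    """Input is well-formed but outside the supported conversion scope
    (e.g. 4D multi-component images)."""


class TooManyLabelsError(FormatError):
    """A label image holds more than the 30 distinct nonzero values the
    segmentation representation supports."""


class EmptyLabelMapError(FormatError):
    """A label image contains no nonzero voxels."""


class EmptyTractError(FormatError):
    """A tractogram contains no streamlines."""


class CorruptFrameError(FormatError):
    """A run-length-encoded frame cannot be decoded."""


class CorruptObjectError(FormatError):
    """An emitted DICOM object violates its own internal indexing rules."""


class GeometryError(ConversionError):
    exit_code = 4


class UnsupportedGeometryError(GeometryError):
    """An affine cannot be represented as orthogonal DICOM slice geometry."""


class NoMatchingReferenceError(GeometryError):
    """A label image matches none of the structural images' grids."""
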