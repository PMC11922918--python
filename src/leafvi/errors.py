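"""Exception hierarchy shared across the pipeline.

Every error raised by leafvi derives from :class:`LeafVIError`, so callers
(and the CLI exit-code mapping) can catch the whole family at once.
"""


class LeafVIError(Exception):
    """Base class for all leafvi errors."""


# --- ENVI I/O ---------------------------------------------------------------

class EnviHeaderError(LeafVIError):
    """A problem with an ENVI header."""


class MissingField(EnviHeaderError):
    """A required header key (samples/lines/bands/interleave/data type) is absent."""


class InconsistentHeader(EnviHeaderError):
    """Header fields contradict each other (e.g. wavelength count != bands)."""


class UnsupportedDataType(EnviHeaderError):
    """ENVI data type code outside the supported set (4 = float32, 12 = uint16)."""


class SizeMismatch(LeafVIError):
    """Raw buffer length does not match samples * lines * bands * itemsize."""


# --- segmentation / ROI -----------------------------------------------------

class DegenerateHistogram(LeafVIError):
    """Histogram with fewer than two occupied bins: no threshold exists."""


class EmptySegmentation(LeafVIError):
    """Greenness masking / thresholding removed every pixel."""


class InvalidROI(LeafVIError):
    """ROI coordinates violate 0 <= x1 < x2 <= W, 0 <= y1 < y2 <= H."""


class AlignmentError(LeafVIError):
    """RGB frame and spectral cube have different spatial dimensions."""


# --- spectral / VI ----------------------------------------------------------

class UnresolvableWavelength(LeafVIError):
    """Cube carries no wavelength axis, so a wavelength cannot be resolved."""


class NonPositiveReflectance(LeafVIError):
    """Reciprocal-form index (ARI/CRI) evaluated on reflectance <= 0."""


class ZeroDenominator(LeafVIError):
    """Normalized-difference index with a zero denominator."""


class DuplicateName(LeafVIError):
    """A vegetation index with this name is already registered."""


# --- validation -------------------------------------------------------------

class ZeroReference(LeafVIError):
    """Percent error undefined for a zero reference value."""


class DegenerateX(LeafVIError):
    """OLS with a constant predictor."""


class TooFewPoints(LeafVIError):
    """OLS needs at least 3 points."""


class IdMismatch(LeafVIError):
    """Reference and candidate tables do not carry identical id sequences."""


# --- phantom / IO -----------------------------------------------------------

class GenerationFailure(LeafVIError):
    """Phantom spectrum sampling failed to find valid anchors within the attempt budget."""


class IOFailure(LeafVIError):
    """File could not be read or written."""
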