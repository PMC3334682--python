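"""Exception and warning types shared across the package."""


class CardiospecError(Exception):
    """Base class for all cardiospec errors."""


class InvalidParameterError(CardiospecError, ValueError):
    """A model or config parameter violates its stated invariant."""


class GeometryError(CardiospecError, ValueError):
    """A simulated heart does not fit inside the frame at maximal dilation."""


class FormatError(CardiospecError, ValueError):
    """An on-disk artifact violates its documented layout."""


class RoiValidationError(CardiospecError, ValueError):
    """An ROI definition violates the JSON schema; names the offending field."""


class DegenerateRoiError(CardiospecError, ValueError):
    """An ROI rasterizes to an empty pixel set."""


class UnderdeterminedFitError(CardiospecError, ValueError):
    """Trend fit requested with more coefficients than data points support."""


class DataError(CardiospecError, ValueError):
    """Input samples are unusable (non-finite values, non-positive baseline...)."""


class TooShortError(CardiospecError, ValueError):
    """Trace too short for spectral estimation."""


class IncompatibleSpectraError(CardiospecError, ValueError):
    """Two spectra cannot be compared (different sampling rates)."""


class InsufficientDataError(CardiospecError, ValueError):
    """A segment is too short for the requested analysis."""


class ProtocolError(CardiospecError, ValueError):
    """A screening session violates the baseline/compound/wash ordering."""


class TruncatedWindowWarning(UserWarning):
    """A response window extends past the end of the recording."""
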