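"""Exception types raised across the pipeline."""


class SinusLMSError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SinusLMSError, ValueError):
    """Malformed or inconsistent input data (mixed DICOM series, bad geometry)."""


class GeometryError(SinusLMSError, ValueError):
    """Invalid phantom geometry (out-of-bounds or overlapping regions)."""


class NormalizationError(SinusLMSError, ValueError):
    """Intensity normalization impossible (e.g. constant-intensity volume)."""


class ShapeMismatchError(SinusLMSError, ValueError):
    """Paired arrays or transforms do not share the expected shape."""


class ConfigurationError(SinusLMSError, ValueError):
    """Invalid network or pipeline configuration."""
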