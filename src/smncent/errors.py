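"""Exception hierarchy for the smncent pipeline."""


class SmncentError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SmncentError):
    """A file could not be read as the expected image format."""


class DimensionalityError(SmncentError):
    """An image had the wrong number of dimensions for its role."""


class GeometryError(SmncentError):
    """Two objects that must share a voxel grid do not."""


class ParameterError(SmncentError, ValueError):
    """A numeric parameter is outside its valid range."""


class CapacityError(SmncentError):
    """A requested synthetic structure does not fit in the grid."""


class DegenerateMapError(SmncentError):
    """A map is degenerate for the requested operation (e.g. zero mean)."""


class LengthError(SmncentError):
    """A time dimension is too short for the requested operation."""


class SampleSizeError(SmncentError):
    """Too few observations for the requested model."""


class ConfigurationError(SmncentError):
    """Inconsistent or invalid run configuration."""
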