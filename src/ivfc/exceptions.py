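"""Exception taxonomy for the IVFC toolkit.

Every error raised on a user-facing path derives from :class:`IVFCError` so
callers (and the CLI) can catch one base class.
"""


class IVFCError(Exception):
    """Base class for all toolkit errors."""


class InvalidMeasurementError(IVFCError, ValueError):
    """A physical quantity violated its domain (non-positive time, volume, ...)."""


class MetadataError(IVFCError, ValueError):
    """Scan metadata missing, unparsable, or violating its invariants."""


class FormatError(IVFCError, ValueError):
    """Image data inconsistent with the declared metadata or an unsupported layout."""


class DataError(IVFCError, ValueError):
    """Tabular or pixel data violating a contract (NaN pixels, duplicate keys, ...)."""


class ConfigError(IVFCError, ValueError):
    """Invalid analysis or simulation configuration."""


class DegenerateImageError(IVFCError, ValueError):
    """An image with no usable intensity structure (e.g. constant)."""


class VesselNotFoundError(IVFCError, ValueError):
    """No vessel lumen detectable in the dye channel."""


class GeometryError(ConfigError):
    """Simulated geometry does not fit the scan line."""


class DegenerateDataError(IVFCError, ValueError):
    """Statistical input with no variance where variance is required."""
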