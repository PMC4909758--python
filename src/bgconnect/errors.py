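"""Exception taxonomy for the bgconnect pipeline.

Every stage raises a subclass of :class:`BgConnectError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class BgConnectError(Exception):
    """Base class for all bgconnect errors."""


class FormatError(BgConnectError):
    """A file does not conform to its declared format (bad magic line,
    non-invertible affine, NaNs in a label volume, ...)."""


class UnsupportedDatatypeError(FormatError):
    """A TCK payload datatype other than Float32LE/Float32BE."""


class CorruptFileError(FormatError):
    """A structurally valid header with an inconsistent or truncated payload."""


class PhantomSpecError(BgConnectError):
    """An invalid phantom specification (overlapping geometries, unknown
    structure names, ...)."""


class GenerationError(BgConnectError):
    """Streamline synthesis could not satisfy its route contract
    (e.g. an arc route with no corridor around the obstacle)."""


class ConfigError(BgConnectError):
    """An invalid pipeline or analysis configuration."""
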