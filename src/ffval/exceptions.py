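"""Exception hierarchy shared across the package."""


class FfvalError(Exception):
    """Base class for all package errors."""


class FormatError(FfvalError):
    """Input file violates the expected format."""


class MissingAtomError(FfvalError):
    """A required atom is absent from the topology."""


class DegenerateGeometryError(FfvalError):
    """Geometry is degenerate (too few or collinear atoms)."""


class UnderdeterminedError(FfvalError):
    """A fit has fewer independent observations than parameters."""


class ConfigError(FfvalError):
    """Pipeline configuration is invalid; message names the field."""
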