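"""Exception types shared across the package."""


class WoodvarError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WoodvarError):
    """An invalid configuration value; the message names the field."""


class NestingError(WoodvarError):
    """Hierarchy labels do not form a proper nesting."""


class DegenerateDataError(WoodvarError):
    """Input carries no usable variance for the requested operation."""


class DesignError(WoodvarError):
    """A hierarchy design is degenerate (e.g. a level with zero dof)."""


class SelectionError(WoodvarError):
    """A resampling selection cannot satisfy its group constraints."""
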