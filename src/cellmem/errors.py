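"""Exception hierarchy.

Every error raised by the package derives from :class:`CellmemError` so callers
can catch package failures with a single except clause; configuration loading
raises the more specific subclasses so each failure mode stays distinguishable.
"""


class CellmemError(Exception):
    """Base class for all cellmem errors."""


class ParameterError(CellmemError, ValueError):
    """A parameter value is outside its documented range or inconsistent."""


class ConfigError(CellmemError):
    """Base class for configuration-file problems."""


class ConfigFileError(ConfigError):
    """The configuration file is missing or unreadable."""


class ConfigParseError(ConfigError):
    """The configuration file is not valid YAML / not a mapping."""


class UnknownKeyError(ConfigError):
    """The configuration contains keys the package does not define."""


class OutOfRangeError(ConfigError, ParameterError):
    """A configuration value parsed fine but violates its range."""


class MonotonicityError(ParameterError):
    """A configured survival or cost form violates its monotonicity contract."""


class StreamExhausted(CellmemError, RuntimeError):
    """A recorded uniform stream was consumed past its end."""


class FixtureError(CellmemError, KeyError):
    """An unknown test-fixture name was requested."""


class ExtinctionError(CellmemError, RuntimeError):
    """An operation that requires a non-empty population got an empty one."""
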