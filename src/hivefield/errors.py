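"""Exception hierarchy for hivefield.

All package-raised errors derive from :class:`HiveFieldError` so callers can
catch one base class; subclasses also inherit the closest builtin
(``ValueError``, ``IOError``, ...) so idiomatic handling keeps working.
"""


class HiveFieldError(Exception):
    """Base class for all hivefield errors."""


class FormatError(HiveFieldError, ValueError):
    """Byte stream does not start with a known magic / supported version."""


class CorruptionError(HiveFieldError, ValueError):
    """Byte stream is structurally damaged (e.g. truncated mid-frame)."""


class SampleRangeError(HiveFieldError, ValueError):
    """A sample value cannot be represented in the 24-bit signed range."""


class SchemaError(HiveFieldError, ValueError):
    """A tabular input is missing required columns or violates its schema."""


class ParameterError(HiveFieldError, ValueError):
    """A simulator or detector parameter is outside its documented domain."""


class ScenarioError(HiveFieldError, ValueError):
    """A scenario is internally inconsistent (overlaps, out-of-range spans)."""


class ConfigurationError(HiveFieldError, ValueError):
    """A band / filter / detector configuration cannot be realised."""


class InsufficientDataError(HiveFieldError, ValueError):
    """Not enough data to compute the requested quantity."""


class UsageError(HiveFieldError, TypeError):
    """An operation was called on an object it is not defined for."""
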