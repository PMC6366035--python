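"""Exception types raised across the package.

All inherit from :class:`ValueError` so callers that do not care about the
distinction can catch a single built-in type.
"""


class InvalidArgumentError(ValueError):
    """An argument is outside its documented domain."""


class ShapeError(ValueError):
    """Array or table dimensions do not conform."""


class DataError(ValueError):
    """Input records are inconsistent (duplicates, id mismatches, non-finite)."""


class ConfigurationError(ValueError):
    """A configuration mapping is incomplete or references unknown keys."""


class SequenceParseError(ValueError):
    """A nucleotide or dot-bracket string contains invalid characters."""
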