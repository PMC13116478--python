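"""Exception hierarchy for the pipeline.

All pipeline-raised errors derive from :class:`RcdError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class RcdError(Exception):
    """Base class for all pipeline errors."""


class ParseError(RcdError):
    """A file or label could not be parsed; the message names the offender."""


class ValidationError(RcdError):
    """An in-memory object violates a container invariant."""


class ConfigError(RcdError):
    """A run or simulation configuration is invalid or infeasible."""


class SchemaError(RcdError):
    """An on-disk intermediate is missing required columns or keys."""
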