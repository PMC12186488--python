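"""Exception hierarchy shared by all stages.

Exit-code mapping used by the CLI: :class:`SchemaError` and
:class:`ConfigError` exit with 2, :class:`ValidationError` (including
:class:`ParseError`) with 3.
"""


class GoCollapseError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(GoCollapseError):
    """Invalid run configuration (bad paths, out-of-range thresholds)."""


class SchemaError(GoCollapseError):
    """An input table lacks a required column or has the wrong layout."""


class ValidationError(GoCollapseError):
    """Input content violates an invariant (cycles, duplicates, bad counts)."""


class ParseError(ValidationError):
    """A stream could not be parsed; the message names the offending line."""
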