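"""Exception hierarchy.

``DataError`` covers everything wrong with user-supplied data (parse
failures, invariant violations, degenerate inputs); the CLI maps it to
exit code 2.
"""


class SettingLinkError(Exception):
    """Base class for all package errors."""


class DataError(SettingLinkError):
    """Invalid or degenerate input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(DataError):
    """An in-memory object violates a structural invariant."""
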