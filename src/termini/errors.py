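"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/format problems -> 2,
configuration/design problems -> 3.
"""


class TerminiError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(TerminiError):
    """Invalid values handed to an operation (bad p-values, negative window, ...)."""

    exit_code = 2


class FormatError(InputError):
    """A file does not conform to its declared format."""


class SamFormatError(FormatError):
    """Malformed SAM record or header."""


class GffFormatError(FormatError):
    """Malformed GFF3 record."""


class UnknownRepliconError(InputError):
    """A record refers to a replicon absent from the reference set."""


class ConfigError(TerminiError):
    """Inconsistent configuration (mismatched libraries, bad thresholds, ...)."""

    exit_code = 3


class DesignError(ConfigError):
    """Sample design that cannot support the requested analysis."""
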