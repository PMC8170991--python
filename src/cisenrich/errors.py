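"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, any other
CisEnrichError -> 3.
"""


class CisEnrichError(Exception):
    """Base class for all errors raised by cisenrich."""


class FormatError(CisEnrichError):
    """A file could not be parsed (malformed line, missing columns, ...)."""


class ValidationError(CisEnrichError):
    """Parsed data violates an invariant (inverted interval, duplicate ID, ...)."""


class ConfigError(CisEnrichError):
    """A configuration file or option set is invalid."""


class DataError(CisEnrichError):
    """A computation cannot proceed on the given data (empty query, ...)."""
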