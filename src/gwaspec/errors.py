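"""Exception hierarchy shared across the package.

``ConfigError`` and ``DataError`` map onto the CLI's exit codes (2 and 3);
library users catch them like any other ``ValueError``.
"""


class GwaspecError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GwaspecError):
    """A configuration value is missing, malformed, or out of its domain."""

    exit_code = 2


class DataError(GwaspecError):
    """Input data violate a contract (missing column, zero rows, duplicates...)."""

    exit_code = 3
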