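"""Error hierarchy shared across the package.

All three derive from ValueError so callers that just validate inputs can
catch the standard type, while the pipeline can tag failures by stage.
"""


class SGNCError(ValueError):
    """Base class for all package errors."""


class DomainError(SGNCError):
    """An input value is outside the mathematical domain of an operation."""


class ConfigError(SGNCError):
    """A configuration object is inconsistent or incomplete."""


class DataError(SGNCError):
    """A dataset or table is malformed or missing required fields."""
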