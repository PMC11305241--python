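"""Exception hierarchy shared across the package."""


class ThiastatError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ThiastatError, ValueError):
    """Raised when an operation's preconditions on its inputs are violated."""


class ConfigurationError(ThiastatError, ValueError):
    """Raised when a configuration is internally inconsistent or unusable."""


class FitError(ThiastatError, RuntimeError):
    """Raised when every candidate fit fails and no result can be returned."""
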