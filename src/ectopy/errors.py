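"""Exception types shared across the package."""


class EctopyError(Exception):
    """Base class for package errors."""


class ConfigurationError(EctopyError):
    """A parameter or selector is invalid for the given data."""


class InvalidInputError(EctopyError):
    """Input data violates an operation's preconditions."""
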