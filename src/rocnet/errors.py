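"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when data passed to an operation violates its preconditions."""


class ConfigurationError(ValueError):
    """Raised when an option or parameter value is not recognised or out of range."""
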