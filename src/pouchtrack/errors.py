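"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is invalid.

    The message names the offending field.
    """


class InputValidationError(ValueError):
    """An input record, table or argument violates a documented contract."""
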