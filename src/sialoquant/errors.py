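"""Shared exception types."""


class ConfigurationError(ValueError):
    """A configuration field is missing or outside its allowed range."""


class InputError(ValueError):
    """An input record or table violates the interface contract."""
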