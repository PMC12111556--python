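"""Exception types shared across the package."""


class CTCMarkError(Exception):
    """Base class for package errors."""


class ConfigurationError(CTCMarkError):
    """A configuration value is invalid; the message names the field."""


class InputError(CTCMarkError):
    """An input file or in-memory object violates its contract."""
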