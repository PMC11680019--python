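"""Exception types used across the package."""


class PulsefeatError(Exception):
    """Base class for package errors."""


class ConfigurationError(PulsefeatError):
    """A processing parameter is invalid for the given data (exit code 2)."""


class LoadError(PulsefeatError):
    """An input file could not be read or failed validation."""
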