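"""Exception hierarchy shared across the package."""


class FtcdlatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FtcdlatError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(FtcdlatError):
    """Malformed input data (wrong item counts, bad values, broken invariants)."""


class ProcessingError(FtcdlatError):
    """A recording or epoch could not be processed (no cardiac signal, no trials...)."""
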