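"""Exception hierarchy shared across the package."""


class SchwalearnError(Exception):
    """Base class for all package errors."""


class ConfigError(SchwalearnError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(SchwalearnError):
    """An input outside the domain of an operation (e.g. a non-schwa token
    passed to the formant generator)."""


class DataError(SchwalearnError):
    """Malformed or degenerate data (negative duration, zero variance...)."""


class NumericError(SchwalearnError):
    """A numerical failure (non-finite weight, singular system...)."""


class JoinError(SchwalearnError):
    """A merge between tables failed because keys were missing."""


class FitError(SchwalearnError):
    """Model fitting failed."""
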