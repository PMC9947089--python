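"""Exception hierarchy for the thermodose pipeline."""


class ThermodoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermodoseError):
    """A configuration value is physically or numerically inadmissible."""


class UsageError(ThermodoseError, ValueError):
    """An operation was called with arguments that violate its contract."""


class DataError(ThermodoseError):
    """Input data are malformed or internally inconsistent."""
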