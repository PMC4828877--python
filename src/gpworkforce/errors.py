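"""Exception hierarchy shared across the package."""


class WorkforceError(Exception):
    """Base class for all gpworkforce errors."""


class ConfigError(WorkforceError):
    """Invalid configuration value (non-positive hours, bad scenario factor, ...)."""


class SchemaError(WorkforceError):
    """Malformed input table: bad header, unknown category label, missing entry."""


class ParameterError(WorkforceError):
    """Invalid model parameter (probability out of range, negative rate, ...)."""


class FitError(WorkforceError):
    """Service-profile fitting failure, e.g. positive consultation share with zero cases."""
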