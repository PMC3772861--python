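"""Exception hierarchy used across the package."""


class MiteLifeError(Exception):
    """Base class for all package errors."""


class SchemaError(MiteLifeError):
    """Malformed tabular input: missing columns, bad day grid, wrong dtypes."""


class DataError(MiteLifeError):
    """Input violates an invariant of the experimental design."""


class ConfigurationError(MiteLifeError):
    """A requested analysis is inconsistent with the sampling schedule."""


class FitError(MiteLifeError):
    """Model fitting failed in a way that cannot be expressed as a flag."""
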