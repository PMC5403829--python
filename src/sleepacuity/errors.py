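"""Exception types shared across the package."""


class SleepAcuityError(Exception):
    """Base class for package errors."""


class ConfigurationError(SleepAcuityError, ValueError):
    """An invalid configuration or cohort-spec field."""


class InputError(SleepAcuityError, ValueError):
    """Malformed or out-of-contract input data."""


class InsufficientDataError(SleepAcuityError, ValueError):
    """Too few observations for the requested computation."""


class FittingError(SleepAcuityError, RuntimeError):
    """A model fit could not be carried out."""


class SelectionError(SleepAcuityError, RuntimeError):
    """No feature subset satisfies the selection constraints."""


class DependencyError(SleepAcuityError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
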