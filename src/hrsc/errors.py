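"""Exception taxonomy for the hrsc package."""


class HrscError(Exception):
    """Base class for all hrsc errors."""


class ConfigurationError(HrscError):
    """Invalid configuration value (bad strata plan, non-positive slope, ...)."""


class DomainError(HrscError, ValueError):
    """Physiologically impossible input (target above VO2max, bad ordering, ...)."""


class ProcessingError(HrscError):
    """A data-processing step cannot run on the given series (window too
    short, irregular grid where a regular one is required, ...)."""


class InputError(HrscError, ValueError):
    """Malformed user input (length mismatch, unknown label, ...)."""


class FittingError(HrscError):
    """A model fit failed (rank-deficient design, ...)."""
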