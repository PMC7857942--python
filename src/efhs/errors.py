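"""Exception hierarchy for the eFHS survey pipeline."""


class EfhsError(Exception):
    """Base class for all package errors."""


class ConfigError(EfhsError):
    """Invalid configuration (probabilities out of range, negative n, ...)."""


class DataError(EfhsError):
    """A record violates the data contract (ordering, range, item count)."""


class DegenerateInputError(EfhsError):
    """Input is degenerate for the requested statistic (zero variance, ...)."""


class SampleSizeError(EfhsError):
    """Too few observations for the requested statistic."""


class UnbalancedPanelError(EfhsError):
    """Longitudinal input is not a complete balanced panel."""


class SeparationError(EfhsError):
    """Logistic regression did not converge (perfect/quasi separation)."""
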