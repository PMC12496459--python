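"""Exception taxonomy shared by all kneeload modules."""


class KneeloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KneeloadError):
    """A configuration object violates its invariants."""


class DataError(KneeloadError):
    """Input data are malformed (shape, NaN, inconsistent lengths)."""


class ArgumentError(KneeloadError):
    """An operation was called with out-of-contract arguments."""


class NumericalError(KneeloadError):
    """A computation produced non-finite or undefined values."""


class StateError(KneeloadError):
    """An operation was called before its required state was prepared."""


class TrainingError(KneeloadError):
    """Optimization diverged; carries the epoch index when known."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class DegenerateError(KneeloadError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
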