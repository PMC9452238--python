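"""Exception hierarchy for the caep package."""


class CaepError(ValueError):
    """Base class for all caep-specific errors."""


class DomainError(CaepError):
    """A parameter lies outside its physically meaningful domain."""


class EmptyEpochSetError(CaepError):
    """An operation that requires epochs received none (e.g. after rejection)."""


class InsufficientEpochsError(CaepError):
    """Too few epochs for the requested statistic (e.g. N <= n_bins)."""


class DegenerateCovarianceError(CaepError):
    """The sample covariance of the binned epochs is singular."""


class InconsistentTraceError(CaepError):
    """A staircase trace does not follow the adaptive protocol."""
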