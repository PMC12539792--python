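"""Exception hierarchy shared across the package."""


class IdealObsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IdealObsError, ValueError):
    """Invalid task, chain, or experiment configuration."""


class DimensionError(IdealObsError, ValueError):
    """Array shapes or curve lengths do not match."""


class DataError(IdealObsError, ValueError):
    """A batch or result set does not satisfy an operation's preconditions."""


class TrainingDataError(DataError):
    """Training data missing a class or required ground truth."""


class StateError(IdealObsError, RuntimeError):
    """An empty chain or otherwise unusable sampler state."""


class ChainInitError(StateError):
    """Non-finite log-likelihood at a chain's initial state."""


class ComparisonError(IdealObsError, ValueError):
    """Two EROC curves were not computed on the same evaluation batch."""
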