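"""Exception hierarchy.

``SSVEPIDError`` covers user-facing problems (bad configuration, bad input,
missing artifacts); anything else escaping the library is an internal bug.
"""


class SSVEPIDError(Exception):
    """Base class for all user-facing errors raised by ssvepid."""


class InvalidConfigError(SSVEPIDError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(SSVEPIDError):
    """Input data violates a precondition (shape, finiteness, emptiness)."""


class InvalidBandError(InvalidConfigError):
    """A filter band edge is non-positive or at/above Nyquist."""


class ShortTrialError(InvalidInputError):
    """Trial too short for the zero-phase filter's reflection padding."""


class OutOfRangeWindowError(InvalidInputError):
    """Requested analysis window does not fit inside the trial."""


class MissingChannelError(InvalidInputError):
    """A requested channel name is not present in the trial."""


class DegenerateTrialError(InvalidInputError):
    """Trial carries no signal (zero total power), covariance undefined."""


class InvalidTrainingSetError(InvalidInputError):
    """Training set violates the fitting preconditions (e.g. empty class)."""


class IncompleteDesignError(InvalidInputError):
    """A (subject, block) cell is missing, so block-wise folds cannot be built."""


class InvalidArchitectureError(InvalidConfigError):
    """DFN layer dimensions violate the expand-then-contract constraints."""


class StratificationError(InvalidInputError):
    """A class is absent from the training or validation split."""


class NotEnrolledError(SSVEPIDError):
    """Authentication requested but enrollment artifacts are absent/corrupt."""


class PipelineStageError(SSVEPIDError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
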