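"""Exception types shared across the pipeline."""


class SGCofluxError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(SGCofluxError, ValueError):
    """A parameter violates a precondition (non-positive rate, bad grid, ...)."""


class InvalidInputError(SGCofluxError, ValueError):
    """Input data violates a contract (NaN voltage, mismatched timestamps, ...)."""


class InsufficientDataError(SGCofluxError, ValueError):
    """Too few samples/animals/channels for the requested computation."""


class InsufficientVarianceError(InsufficientDataError):
    """Degenerate (constant) data where spread is required."""


class DegenerateTargetError(SGCofluxError, ValueError):
    """The control target (e.g. LVP) carries no usable amplitude structure."""


class SessionExcludedError(SGCofluxError):
    """Raised when channel-quality screening leaves fewer than two channels."""
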