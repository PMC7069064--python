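"""Exception hierarchy.

Every error raised by lollinet derives from :class:`LollinetError`, so callers
can catch one type. Pipeline stages re-raise with the stage name attached
(see :mod:`lollinet.pipeline`).
"""


class LollinetError(Exception):
    """Base class for all lollinet errors."""


class InvalidSizeError(LollinetError, ValueError):
    """A generator was asked for an impossible graph size or edge count."""


class ConnectivityError(LollinetError, ValueError):
    """The (positive-weight) graph is disconnected; hitting times undefined."""


class DegenerateInputError(LollinetError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero weights)."""


class GenerationError(LollinetError, RuntimeError):
    """A randomized generator failed to produce a valid draw within its
    bounded retry budget."""


class ValidationError(LollinetError, ValueError):
    """An input object violates a structural invariant (asymmetry, NaN,
    label mismatch, non-square table ...)."""


class EstimationError(LollinetError, RuntimeError):
    """A statistical estimate could not be produced (singular covariance,
    excessive Monte-Carlo censoring, undefined skewness ...)."""


class DesignError(LollinetError, ValueError):
    """A model design matrix is unusable (single-level factor, rank
    deficiency, unbalanced pairing)."""


class PipelineError(LollinetError, RuntimeError):
    """Wrapper carrying the pipeline stage at which an error occurred."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[stage: {stage}] {original}")
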