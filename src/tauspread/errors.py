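"""Exception types shared across the pipeline stages."""


class TauspreadError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(TauspreadError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(TauspreadError, ValueError):
    """Too few observations to carry out the requested estimate."""


class FitFailureError(TauspreadError, RuntimeError):
    """A model fit could not be completed (e.g. degenerate sample)."""


class MissingModelError(TauspreadError, KeyError):
    """No fitted harmonization model is available for the requested tracer."""


class CollinearityError(TauspreadError, ValueError):
    """The covariate design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient covariate design; offending columns: {self.columns}")


class EmptyGraphError(TauspreadError, ValueError):
    """A graph operation received a matrix with no usable edges."""


class RewireFailureError(TauspreadError, RuntimeError):
    """The null-model rewiring could not complete on this graph."""
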