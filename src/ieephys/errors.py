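"""Exception hierarchy shared across the package."""


class IeephysError(Exception):
    """Base class for all package-specific errors."""


class TermNotFoundError(IeephysError, KeyError):
    """An ontology term id was looked up but is not in the registry."""


class UnknownSourceError(IeephysError, ValueError):
    """A source name is not one of the recognised ontology sources."""


class SchemaCompileError(IeephysError):
    """The registry cannot be compiled into a file architecture."""


class UnknownUnitError(IeephysError, ValueError):
    """A units string is not in the long-form units table."""


class EstimationError(IeephysError):
    """A parameter estimate could not be obtained from the data.

    Carries the last residual (or iterate) so callers can report how far
    the estimator got before giving up.
    """

    def __init__(self, message, residual=None, last_iterate=None):
        super().__init__(message)
        self.residual = residual
        self.last_iterate = last_iterate


class FitError(EstimationError):
    """A nonlinear least-squares fit failed or was degenerate."""


class SchemaError(IeephysError):
    """A bundle or file is missing schema-required content.

    ``paths`` lists every missing location so the caller sees the full
    deficit at once rather than one item per attempt.
    """

    def __init__(self, message, paths=()):
        super().__init__(message)
        self.paths = list(paths)


class PipelineError(IeephysError):
    """A transformation stage failed; partial results are preserved."""

    def __init__(self, message, stage, partial=None):
        super().__init__(message)
        self.stage = stage
        self.partial = partial
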