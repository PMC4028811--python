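"""Error hierarchy for arrayimpute.

Every failure mode a caller may want to branch on gets its own class;
all inherit from :class:`ArrayImputeError`.
"""


class ArrayImputeError(Exception):
    """Base class for all arrayimpute errors."""


class FormatError(ArrayImputeError):
    """A file could not be parsed as an expression matrix."""


class ValidationError(ArrayImputeError):
    """An in-memory object violates its contract (duplicate IDs, shape mismatch ...)."""


class ParameterError(ArrayImputeError):
    """A configuration value is out of its allowed range."""


class MaskingError(ArrayImputeError):
    """Missing-value injection could not satisfy its guard conditions."""


class EmptyResultError(ArrayImputeError):
    """An operation produced an empty result where at least one row is required."""


class MetricUndefinedError(ArrayImputeError):
    """A performance index is mathematically undefined for the given inputs."""


class DesignError(ArrayImputeError):
    """A statistical design is unusable (e.g. a class with fewer than two samples)."""


class NumericalError(ArrayImputeError):
    """An iterative estimator collapsed numerically; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SelectionError(ArrayImputeError):
    """No algorithm could be scored, so no optimum can be selected."""
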