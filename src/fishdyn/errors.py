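"""Exception types shared across the pipeline."""


class FishdynError(Exception):
    """Base class for package-specific failures."""


class InsufficientDataError(FishdynError):
    """Raised when an operation receives fewer observations than it needs."""


class DegenerateFitError(FishdynError):
    """Raised when an estimator collapses (e.g. a mixture component onto a point)."""


class NoBoundaryError(FishdynError):
    """Raised when no crossing point exists between two mixture components."""


class SchemaMismatchError(FishdynError):
    """Raised when an external file does not contain the expected variables."""

    def __init__(self, message: str, found=None):
        super().__init__(message)
        self.found = list(found) if found is not None else []


class StageDependencyError(FishdynError):
    """Raised when a pipeline stage is requested without its upstream outputs."""
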