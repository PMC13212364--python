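"""Exception hierarchy for the phenostat pipeline."""


class PhenostatError(Exception):
    """Base class for all phenostat errors."""


class CoordinateParseError(PhenostatError):
    """A unit coordinate string does not parse as ``block:row:index``."""


class ProjectLayoutError(PhenostatError):
    """The project directory does not match the expected file layout."""


class ProjectValidationError(PhenostatError):
    """Project tables fail validation; carries the report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class UndefinedIndexError(PhenostatError):
    """A spectral index is undefined for the given band values."""


class DegenerateDesignError(PhenostatError):
    """The experimental design cannot support the requested model."""


class ConvergenceError(PhenostatError):
    """An iterative model fit failed to converge; carries optimizer details."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details


class ConfigError(PhenostatError):
    """A run configuration is malformed or contains unknown keys."""
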