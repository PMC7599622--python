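"""Exception types shared across the package."""


class GapRunnerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GapRunnerError):
    """Invalid schedule, profile, or run configuration."""


class DataFormatError(GapRunnerError):
    """Malformed on-disk log or cohort file.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateDataError(GapRunnerError):
    """Statistic undefined on the given data (constant input, too few points)."""


class SingularDesignError(GapRunnerError):
    """Regression design matrix is rank deficient."""
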