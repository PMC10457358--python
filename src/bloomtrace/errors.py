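"""Exception hierarchy shared across the package."""


class BloomtraceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BloomtraceError, ValueError):
    """Invalid argument or inconsistent input data."""


class FormatError(BloomtraceError, ValueError):
    """A file on disk does not match the expected layout."""


class ConfigurationError(BloomtraceError, ValueError):
    """A sensor or pipeline configuration is unusable."""


class EmptySceneError(BloomtraceError):
    """An operation required at least one valid pixel and found none."""


class NoThresholdError(BloomtraceError):
    """Automatic threshold selection found no usable candidate."""


class UndefinedStatisticError(BloomtraceError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class DegenerateSeriesError(BloomtraceError):
    """A series has no usable variation (e.g. zero innovation variance)."""


class FitConvergenceError(BloomtraceError):
    """Model estimation failed to converge.

    Carries ``last_params`` (the optimizer's final iterate) for diagnosis.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class CollinearityError(ValidationError):
    """Design matrix is rank deficient; ``columns`` names the offenders."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class StageError(BloomtraceError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
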