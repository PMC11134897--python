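"""Exception hierarchy shared by all stages of the pipeline."""


class HRVReactError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HRVReactError, ValueError):
    """Invalid parameter combination (non-positive durations, amplitude overflow...)."""


class InsufficientDataError(HRVReactError, ValueError):
    """Not enough beats/values to carry out the requested computation."""


class DegenerateInputError(HRVReactError, ValueError):
    """Input with zero variance or empty margins where a statistic is undefined."""


class NonPositiveDataError(HRVReactError, ValueError):
    """A log10 transform was triggered on data containing non-positive values.

    The caller must decide whether to offset or exclude; nothing is done silently.
    """


class UndefinedROCError(HRVReactError, ValueError):
    """ROC analysis requested with only one class present."""


class MissingDataError(HRVReactError, ValueError):
    """A required cell/recording is absent (no imputation is performed)."""
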