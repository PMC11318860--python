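"""Exception hierarchy."""


class ChillconnError(Exception):
    """Base class for package errors."""


class InvalidConfigError(ChillconnError, ValueError):
    """A configuration value violates its stated constraints."""


class InsufficientDataError(ChillconnError, ValueError):
    """Too few samples/peaks/volumes for the requested operation."""


class InvalidBandError(ChillconnError, ValueError):
    """Filter band incompatible with the sampling rate."""


class WindowRangeError(ChillconnError, ValueError):
    """Requested time window lies outside the epoch."""


class UndefinedCorrelationError(ChillconnError, ValueError):
    """Correlation undefined (constant signal); message names the ROI."""


class EmptyAverageError(ChillconnError, ValueError):
    """All inputs to an average were missing."""


class SamplingError(ChillconnError, ValueError):
    """Random window sampling infeasible for the requested geometry."""


class AlignmentError(ChillconnError, ValueError):
    """Feature/edge identities do not match between model and data."""


class UndefinedResponseError(ChillconnError, ValueError):
    """Percent-signal-change baseline non-positive; message names the ROI."""


class GenerationError(ChillconnError, ValueError):
    """Synthetic-cohort generation infeasible under the configuration."""


class BoundedSearchError(ChillconnError, ValueError):
    """A bounded numeric search exhausted its range."""


class PipelineInputError(ChillconnError, ValueError):
    """Missing or malformed pipeline input; message names the file."""
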