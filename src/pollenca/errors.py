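"""Exception hierarchy. Everything raised on bad user input derives from ValueError."""


class PollencaError(Exception):
    """Base class for all pollenca errors."""


class InvalidInputError(PollencaError, ValueError):
    """A value violates a documented precondition."""


class FormatError(PollencaError, ValueError):
    """A trace/ROI table is malformed (missing columns, duplicate rows, ragged grid)."""


class AlignmentError(PollencaError, ValueError):
    """Two traces that must share a time grid do not."""


class NoStableBaselineError(PollencaError):
    """No window of frames satisfies the baseline stability criterion."""


class InvalidBaselineError(PollencaError, ValueError):
    """Baseline window is out of range or has non-positive mean fluorescence."""


class BleachFitError(PollencaError):
    """Both exponential and linear photobleaching fits failed."""


class InvalidRoiError(PollencaError, ValueError):
    """An ROI disc falls outside the image bounds."""


class InvalidLayoutError(PollencaError, ValueError):
    """Synthetic grain layout is invalid (overlap or out of frame)."""


class ConfigMismatchError(PollencaError, ValueError):
    """Cohort members were analyzed with different configurations."""


class NormalizationError(PollencaError, ValueError):
    """Growth normalization has no usable matched control."""


class UndefinedIndexError(PollencaError, ValueError):
    """Desensitization index is undefined (first peak is zero)."""
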