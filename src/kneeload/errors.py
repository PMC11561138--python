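"""Exception hierarchy for the kneeload toolkit."""


class KneeloadError(Exception):
    """Base class for all kneeload-specific errors."""


class InvalidArgumentError(KneeloadError, ValueError):
    """An argument violated a documented precondition."""


class NoStanceError(KneeloadError):
    """No suprathreshold ground-contact interval was found."""


class InsufficientCyclesError(KneeloadError):
    """Fewer than two gait events detected; no gait period can be formed."""


class MissingStreamError(KneeloadError, KeyError):
    """A required sensor site is absent from the stream bundle."""


class CalibrationError(KneeloadError):
    """Pixel-to-metre calibration could not be established."""


class InsufficientDataError(KneeloadError):
    """Too few accepted frames/samples for a reliable estimate."""


class LowQualityError(KneeloadError):
    """More than half of the frames fall below the confidence threshold."""


class SingularDesignError(KneeloadError):
    """The regression design matrix is rank deficient."""


class TrainingFailureError(KneeloadError):
    """Network training produced a non-finite objective."""
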