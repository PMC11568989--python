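"""Exception hierarchy shared across the pipeline stages."""


class GaitFallError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(GaitFallError, ValueError):
    """Arguments violate an operation's preconditions."""


class DegenerateSignalError(GaitFallError, ValueError):
    """A signal is unusable (e.g. identically zero on one axis)."""


class DegenerateSpectrumError(GaitFallError, ValueError):
    """The in-band power spectrum carries no usable power."""


class NoStepsDetectedError(GaitFallError, RuntimeError):
    """Step detection found too few plausible step peaks."""


class InvalidKError(InvalidInputError):
    """ReliefF neighbor count exceeds what a class can supply."""


class CohortInvalidError(GaitFallError, ValueError):
    """A cohort is missing a class or is otherwise not evaluable."""


class TrainingFailedError(GaitFallError, RuntimeError):
    """Classifier training could not proceed on the given matrix."""


class UndefinedMetricError(GaitFallError, ZeroDivisionError):
    """A confusion-matrix metric has a zero denominator."""
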