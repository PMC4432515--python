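"""Exception hierarchy for confsim."""


class ConfsimError(Exception):
    """Base class for all confsim-specific errors."""


class ValidationError(ConfsimError, ValueError):
    """Invalid user input (bad anchors, out-of-range parameters, malformed config)."""


class CalibrationError(ConfsimError, RuntimeError):
    """A calibration routine could not meet its tolerance.

    Carries the achieved values so the caller can inspect how far off the
    calibration landed.
    """

    def __init__(self, message: str, achieved=None):
        super().__init__(message)
        self.achieved = achieved


class InfeasibleTargetError(CalibrationError):
    """Requested discrimination target exceeds the population's intrinsic ceiling."""


class UndefinedAUROCError(ConfsimError, ValueError):
    """AUROC is undefined because only one outcome class is present."""
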