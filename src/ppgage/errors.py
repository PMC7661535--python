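"""Exception hierarchy shared across the pipeline."""


class PPGAgeError(Exception):
    """Base class for all package errors."""


class FormatError(PPGAgeError):
    """A recording or table file does not match the expected dialect."""


class EmptyInputError(PPGAgeError):
    """An input file or vector is empty where data is required."""


class EmptyCohortError(PPGAgeError):
    """Cohort assembly dropped every subject."""


class SignalError(PPGAgeError):
    """A signal-level precondition is violated (length, monotonicity, ...)."""


class FeatureMissingError(PPGAgeError):
    """A feature family could not be computed for a recording."""

    def __init__(self, family: str, reason: str = ""):
        self.family = family
        self.reason = reason
        msg = f"feature family '{family}' unavailable"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)
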