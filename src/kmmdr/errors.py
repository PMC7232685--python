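"""Exception hierarchy for kmmdr."""


class KmmdrError(Exception):
    """Base class for all kmmdr errors."""


class InvalidInputError(KmmdrError, ValueError):
    """Malformed or empty input (wrong shapes, bad codes, n < k, ...)."""


class DegenerateGroupError(KmmdrError):
    """A two-sample statistic was requested with an empty group."""


class UndefinedStatisticError(KmmdrError):
    """The requested statistic has zero variance and is undefined."""


class MethodNotApplicableError(KmmdrError):
    """The classifier cannot run on this sample.

    Raised by the Kaplan-Meier median classifier when the overall median
    survival time is not estimable (heavy censoring / cure fraction).
    """


class FitFailureError(KmmdrError):
    """A null regression model (Cox or AFT) failed to converge."""

    def __init__(self, message: str, diagnostics: object = None):
        super().__init__(message)
        self.diagnostics = diagnostics


class NoModelError(KmmdrError):
    """Model selection was asked to choose among zero usable candidates."""


class CalibrationError(KmmdrError):
    """Censoring calibration could not reach the requested fraction."""

    def __init__(self, message: str, achievable: tuple | None = None):
        super().__init__(message)
        self.achievable = achievable


class ParseError(KmmdrError, ValueError):
    """A data file failed validation; the message names the location."""
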