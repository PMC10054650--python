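"""Exception hierarchy for bioassay analysis failures.

Every error a caller may want to catch programmatically has its own class;
all inherit from :class:`BtassayError`.
"""


class BtassayError(Exception):
    """Base class for all package-specific errors."""


class InvalidControlError(BtassayError):
    """Control mortality of 100%: no surviving baseline for Abbott's correction."""


class DegenerateDataError(BtassayError):
    """Response data carry no dose-response signal (all dead, all alive,
    flat mortality, or complete separation).  The caller should report a
    censored LC50 via the activity screen instead of a fit."""


class ConvergenceError(BtassayError):
    """Newton-Raphson failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, iterations=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.iterations = iterations


class NonMonotoneFitError(BtassayError):
    """Fitted slope is not positive, so LCp inversion is meaningless."""


class UnboundedLimitsError(BtassayError):
    """Fieller g >= 1: slope not significantly positive, limits unbounded."""


class UnsupportedCensorError(BtassayError):
    """A less-than-censored LC50 cannot enter the simple-similar-action sum."""


class MissingDataError(BtassayError):
    """Required observations are absent (e.g. empty mortality map)."""


class DesignError(BtassayError):
    """Invalid assay design (non-decreasing dose series, dilution factor <= 1...)."""


class SchemaError(BtassayError):
    """Input file violates the bioassay schema; names the row and column."""

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class UnknownTreatmentError(BtassayError):
    """A mixture definition references a treatment absent from the fit report."""
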