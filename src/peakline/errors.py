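"""Exception hierarchy for peakline.

All library-specific failures derive from :class:`PeaklineError` so callers
can catch the whole family; I/O-flavoured errors additionally derive from
``OSError`` to honour the usual file-error contracts.
"""


class PeaklineError(Exception):
    """Base class for all peakline errors."""


class MzMLReadError(PeaklineError, OSError):
    """The mzML file is absent, unreadable or malformed."""


class MzMLWriteError(PeaklineError, OSError):
    """The mzML file could not be written."""


class EmptyRunError(PeaklineError):
    """An mzML file contained no MS1 spectra."""


class SchemaError(PeaklineError):
    """A tabular input is missing required columns."""


class RowValidationError(PeaklineError):
    """A row of a tabular input violates a field invariant."""

    def __init__(self, cpd_id: str, field: str, message: str):
        self.cpd_id = cpd_id
        self.field = field
        super().__init__(f"invalid ROI row {cpd_id!r} (field {field!r}): {message}")


class NoSignalError(PeaklineError):
    """The chromatogram carries no usable signal."""


class InsufficientDataError(PeaklineError):
    """Too few data points for the requested operation."""


class UndefinedMetricsError(PeaklineError):
    """Peak metrics requested on a non-converged fit."""


class CalibrationError(PeaklineError):
    """Retention-time calibration failed to reach consensus."""


class InversionError(PeaklineError):
    """A retention-time mapping cannot be inverted on the requested range."""


class BatchError(PeaklineError):
    """Every file in a batch failed."""


class ConfigError(PeaklineError):
    """Invalid run configuration."""
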