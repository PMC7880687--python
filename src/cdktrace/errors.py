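"""Exception hierarchy shared across the package."""


class CdkTraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CdkTraceError):
    """A simulation or run configuration violates its invariants."""


class SchemaError(CdkTraceError):
    """A trace table is missing required columns."""


class ParseError(CdkTraceError):
    """A trace table contains malformed rows; the message names them."""


class RoiError(CdkTraceError):
    """ROI masks are empty, overlapping, or mismatched in shape."""


class DegenerateMeasurementError(CdkTraceError):
    """Nuclear mean intensity of zero — the ratio is undefined.

    Usually signals that background subtraction removed the entire signal.
    """


class CoverageError(CdkTraceError):
    """A trace does not cover the timepoints an operation needs."""


class InputError(CdkTraceError):
    """Empty or otherwise unusable input to a statistical routine."""


class GridError(CdkTraceError):
    """Mean trend lines are defined on mismatched time grids."""


class SizeError(CdkTraceError):
    """Input too large for exhaustive enumeration."""


class DegenerateLabelsError(CdkTraceError):
    """Only one fate class present where both are required."""


class TrainingError(CdkTraceError):
    """Classifier training produced no usable timepoint."""


class StratificationError(CdkTraceError):
    """A fate class has too few traces for a stratified split."""
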