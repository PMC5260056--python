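"""Exception hierarchy shared across the package."""


class CMINetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CMINetError):
    """Input violates a structural precondition (labels, shapes, finiteness)."""


class InsufficientDataError(InvalidInputError):
    """Too few observations to estimate the requested quantity."""


class DegenerateCovarianceError(CMINetError):
    """Covariance determinant at or below the numerical floor."""


class DegenerateScanError(CMINetError):
    """Edge-count scan carries no decay signal (all counts equal)."""


class DegenerateFitError(CMINetError):
    """Fitted decay curve has parallel start/end tangents."""


class UndefinedCurveError(CMINetError):
    """ROC/PR curves undefined (gold standard lacks positives or negatives)."""


class FormatError(InvalidInputError):
    """A file does not conform to the expected text dialect."""
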