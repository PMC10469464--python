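"""Exception and warning hierarchy shared across tmfkit modules."""


class TmfkitError(Exception):
    """Base class for all tmfkit errors."""


class MissingPropertyError(TmfkitError):
    """A required physicochemical property or distribution coefficient is absent."""


class UnfitTableError(TmfkitError):
    """A QSPR fit cannot be produced from the supplied points."""


class DegenerateCompositionError(TmfkitError):
    """Tissue composition has no sorbing phase (capacity would be zero)."""


class DomainError(TmfkitError):
    """A physical quantity is outside its valid domain (e.g. nonpositive kelvin)."""


class NonNormalizableSampleError(TmfkitError):
    """The normalization scheme's phase fraction is zero for this sample."""


class CensoringError(TmfkitError):
    """Censored-data statistics refused (too much censoring, no detects, ...)."""


class RegressionError(TmfkitError):
    """Censored regression failed (degenerate design or non-convergence)."""


class InsufficientDataError(TmfkitError):
    """Fewer usable samples than the estimator requires."""


class DetectionFrequencyError(TmfkitError):
    """Analyte fails the detection-frequency gate for TMF estimation."""


class UnknownAnalyteError(TmfkitError):
    """Analyte not present in any sample or in the chemical table."""


class ValidationError(TmfkitError):
    """Input-table validation failed; carries row-level messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


class ExtrapolationWarning(UserWarning):
    """A QSPR prediction used a molar volume outside the fitted range."""


class ExclusionWarning(UserWarning):
    """A sample was excluded from an analysis (with reason)."""


class ClippingWarning(UserWarning):
    """A synthetic composition fraction was clipped to its valid bounds."""
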