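"""Exception hierarchy.

Two broad families: validation errors (bad inputs, bad config — the caller
can fix them) and computation errors (a stage ran on plausible input and
failed). The CLI maps them to exit codes 2 and 3 respectively.
"""


class LfaError(Exception):
    """Base class for all package errors."""


class ValidationError(LfaError):
    """Invalid input, configuration or file layout."""


class ComputationError(LfaError):
    """A processing stage failed on structurally valid input."""


class ConfigError(ValidationError):
    """Missing or inconsistent run configuration."""


class LayoutError(ValidationError):
    """Zone layout inconsistent with the image (out of bounds, overlap)."""


class FormatError(ValidationError):
    """Unexpected array shape or file format."""


class DomainError(ValidationError):
    """A numeric argument outside its physical domain."""


class DetectionError(ComputationError):
    """Fiducial landmarks could not be located in the image."""


class CorrectionError(ComputationError):
    """Illumination correction impossible (too few / collinear points)."""


class DegenerateInputError(ComputationError):
    """Input with no information content (e.g. single-valued histogram)."""


class NoSpotError(ComputationError):
    """Segmentation produced an empty spot class."""


class NormalizationError(ComputationError):
    """Blank (zero-concentration) signal missing or non-positive."""


class FitError(ComputationError):
    """Nonlinear least squares did not converge."""


class BandError(ComputationError):
    """Confidence band undefined (singular covariance)."""


class LimitError(ComputationError):
    """Detection limit outside the calibrated concentration range."""


class ReportError(ComputationError):
    """Report assembly failed (duplicate labels, empty input)."""
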