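"""Exception hierarchy for the perfusion pipeline.

Every stage raises a subclass of :class:`PerfquantError`; the orchestrator
catches these to attach stage/patient context before re-raising.
"""


class PerfquantError(Exception):
    """Base class for all perfquant errors."""


class ParameterError(PerfquantError, ValueError):
    """A parameter violated its documented range."""


class NoBolusDetected(PerfquantError):
    """No pair of consecutive points fell below the baseline threshold."""


class InsufficientBaseline(PerfquantError):
    """Bolus arrived before the minimum baseline length was accumulated."""


class CurveTooShort(PerfquantError):
    """Not enough post-minimum points to run the first-pass-end rule."""


class QCReject(PerfquantError):
    """Bolus depth below the quality-control noise floor."""


class DegenerateReference(PerfquantError):
    """Reference concentration curve carries no usable signal energy."""


class ReferenceUnavailable(PerfquantError):
    """Every reference-tissue voxel failed quality control."""


class TooFewVoxels(PerfquantError):
    """Fewer usable voxels than required for histogram features."""


class ShapeError(PerfquantError, ValueError):
    """Series and mask grids do not agree."""


class GridMismatch(PerfquantError):
    """NIfTI volumes live on different grids (shape or affine)."""


class FormatError(PerfquantError):
    """A file did not have the expected dimensionality or format."""


class StratificationError(PerfquantError):
    """A cross-validation fold lacked one of the two classes."""


class EmptyCandidateSet(PerfquantError):
    """Univariate filtering removed every feature; classification halts."""
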