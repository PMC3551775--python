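"""Exception hierarchy for the amrsid pipeline.

Every stage raises a subclass of :class:`AmrsidError`, so callers (and the
CLI) can catch one type and still name the failing stage.
"""


class AmrsidError(Exception):
    """Base class for all amrsid errors."""


class DimensionalityError(AmrsidError):
    """Image is not a 3D scalar volume."""


class AlignmentError(AmrsidError):
    """Label mask does not share the volume's grid."""


class EmptyRegionError(AmrsidError):
    """Requested region has no voxels (or no such label code)."""


class DegenerateReferenceError(AmrsidError):
    """Reference-tissue mean is zero or negative; normalization undefined."""


class DegenerateDistributionError(AmrsidError):
    """Zero-variance intensity distribution; KS distance undefined."""


class DegenerateIntensityError(AmrsidError):
    """All-zero intensities; intensity-weighted center undefined."""


class ContainmentError(AmrsidError):
    """NP region is not contained in the IVD region."""


class InsufficientDataError(AmrsidError):
    """Too few observations per group for the requested statistical test."""


class DesignError(AmrsidError):
    """Factorial design has an empty cell or missing factor level."""
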