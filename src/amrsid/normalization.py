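"""Reference-tissue intensity normalization.

T2-weighted signal intensities are in arbitrary scanner units that vary with
acquisition gain and sequence parameters, so disc intensities are divided by
the mean intensity of a reference tissue of constant composition — cerebrospinal
fluid (CSF) or the cancellous bone of the vertebra above the disc.  Dividing by
the CSF mean cancels the multiplicative gain exactly; dividing by bone cancels
the gain and additionally folds in vertebral bone remodeling, so the two
references answer different questions about the same disc.

The companion normalization step — weighting each voxel by its fraction of the
region volume — lives in :class:`~amrsid.volumes_io.RegionSample.weights` and is
untouched here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError
from .volumes_io import RegionSample

logger = logging.getLogger(__name__)

REFERENCE_KINDS = ("CSF", "BONE", "NONE")


@dataclass(frozen=True)
class NormalizationResult:
    """Dimensionless intensities after division by a reference-tissue mean."""

    normalized_intensities: np.ndarray
    reference_kind: str  # CSF | BONE | NONE
    reference_mean: float

    def __post_init__(self) -> None:
        if self.reference_kind not in REFERENCE_KINDS:
            raise ValueError(f"reference_kind must be one of {REFERENCE_KINDS}")
        if self.reference_kind != "NONE" and self.reference_mean <= 0:
            raise DegenerateReferenceError(
                f"reference mean must be > 0, got {self.reference_mean}"
            )


def reference_mean(sample: RegionSample) -> float:
    """Volume-weighted mean intensity of a reference region.

    On a uniform grid the weights are all 1/n, so this equals the plain mean.
    Raises :class:`DegenerateReferenceError` when the mean is not positive.
    """
    m = float(np.sum(sample.weights * sample.intensities))
    if m <= 0:
        raise DegenerateReferenceError(
            f"reference region {sample.region_name!r} has non-positive mean {m}"
        )
    return m


def normalize_intensities(
    sample: RegionSample,
    ref: float,
    *,
    reference_kind: str = "CSF",
) -> NormalizationResult:
    """Divide a region's intensities by a reference mean.

    Negative raw intensities (possible in synthetic data with additive noise)
    are clipped to 0 with a warning: magnitude MR images are non-negative.
    """
    if ref <= 0:
        raise DegenerateReferenceError(f"reference mean must be > 0, got {ref}")
    raw = sample.intensities
    if np.any(raw < 0):
        logger.warning(
            "clipping %d negative intensities to 0 in region %s",
            int((raw < 0).sum()),
            sample.region_name,
        )
        raw = np.clip(raw, 0.0, None)
    return NormalizationResult(
        normalized_intensities=raw / ref,
        reference_kind=reference_kind,
        reference_mean=float(ref),
    )


def identity_normalization(sample: RegionSample) -> NormalizationResult:
    """No-op normalization (reference_kind NONE) for debugging phantoms."""
    raw = np.clip(sample.intensities, 0.0, None)
    return NormalizationResult(
        normalized_intensities=raw.copy(), reference_kind="NONE", reference_mean=1.0
    )
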