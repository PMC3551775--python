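"""Intensity-weighted center geometry and NP/IVD volume ratio.

The intensity-weighted center W = sum_i I_i P_i / sum_i I_i of a region and
its unweighted geometric center G coincide for a symmetric disc; degeneration
and nucleus displacement pull W away from G.  The normalized distance
d = |W - G| / N (N the region's voxel count) makes the shift comparable
across discs of different sizes on a common grid.  Note d's units are
mm/voxel when positions are in mm: d divides a physical distance by a count,
so cross-study comparisons require matched resolution (positions in voxel
units are available via ``extract_region(..., units="voxel")``).

The volume ratio between nucleus pulposus and whole disc is a plain voxel
count ratio — integer-exact on a single grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContainmentError, DegenerateIntensityError
from .volumes_io import RegionSample


@dataclass(frozen=True)
class CenterPair:
    """Weighted center W, geometric center G, normalized distance d = |W-G|/N."""

    W: np.ndarray  # (3,) mm
    G: np.ndarray  # (3,) mm
    d: float
    N: int


@dataclass(frozen=True)
class VolumeRatio:
    ratio: float
    np_voxels: int
    ivd_voxels: int


def weighted_center(
    sample: RegionSample,
    intensities: np.ndarray | None = None,
    *,
    volume_weighted: bool = False,
) -> np.ndarray:
    """Intensity-weighted mean position of a region.

    Parameters
    ----------
    intensities:
        Weights for each voxel position; defaults to the sample's raw
        intensities.  Pass normalized intensities to keep the pipeline's
        normalization order (the center is invariant to their scale either
        way).
    volume_weighted:
        Additionally weight by voxel volume fractions — relevant only for
        non-uniform grids; the plain intensity weighting follows the n-point
        sum definition.
    """
    I = sample.intensities if intensities is None else np.asarray(intensities, dtype=float)
    if len(I) != sample.n:
        raise ValueError("intensity vector does not match the region sample")
    if volume_weighted:
        I = I * sample.weights * sample.n
    total = I.sum()
    if total <= 0:
        raise DegenerateIntensityError(
            f"region {sample.region_name!r} has no positive intensity mass"
        )
    return (I[:, None] * sample.positions).sum(axis=0) / total


def geometric_center(sample: RegionSample) -> np.ndarray:
    """Unweighted mean of the region's voxel positions."""
    return sample.positions.mean(axis=0)


def center_distance(
    sample: RegionSample,
    intensities: np.ndarray | None = None,
) -> CenterPair:
    """Normalized distance between weighted and geometric centers, d = |W-G|/N."""
    W = weighted_center(sample, intensities)
    G = geometric_center(sample)
    N = sample.n
    return CenterPair(W=W, G=G, d=float(np.linalg.norm(W - G)) / N, N=N)


def volume_ratio(np_sample: RegionSample, ivd_sample: RegionSample) -> VolumeRatio:
    """Voxel-count ratio of nucleus pulposus to whole disc."""
    n_np, n_ivd = np_sample.n, ivd_sample.n
    if n_np > n_ivd:
        raise ContainmentError(
            f"NP ({n_np} voxels) cannot exceed the IVD ({n_ivd} voxels)"
        )
    return VolumeRatio(ratio=n_np / n_ivd, np_voxels=n_np, ivd_voxels=n_ivd)
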