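"""Volumetric image I/O and per-region voxel sampling.

Volumes and label masks are NIfTI-1/2 images read through nibabel.  A
:class:`LabelMask` maps region names to integer codes; region membership is
hierarchical so that the nucleus pulposus (NP) is a subset of the whole disc
(IVD): the IVD region is the union of the IVD, NP and AF codes, and the
annulus fibrosus (AF) falls back to "IVD minus NP" when the mask carries no
explicit AF code.

Positions are voxel centers mapped through the image affine (0-based voxel
indices, millimetres).  Each voxel carries a volume-fraction weight
``voxel_volume / region_volume`` so downstream histogram indices are Riemann
sums over the region, independent of voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import AlignmentError, DimensionalityError, EmptyRegionError

#: Default region-name -> integer-code convention for label masks.
DEFAULT_LABEL_MAP: dict[str, int] = {"IVD": 1, "NP": 2, "AF": 3, "CSF": 4, "BONE": 5}

#: Regions whose union forms the whole disc.
_IVD_PARTS = ("IVD", "NP", "AF")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar intensity field on a regular grid.

    Attributes
    ----------
    data : ndarray
        3D array of intensities (arbitrary scanner units).
    affine : ndarray
        4x4 voxel-index -> world-mm transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(f"expected a 3D volume, got {data.ndim}D")
        if min(data.shape) < 1:
            raise DimensionalityError(f"degenerate volume shape {data.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class LabelMask:
    """Integer label array aligned with a :class:`VolumeGrid`."""

    labels: np.ndarray
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise DimensionalityError(f"expected a 3D label mask, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("label mask must contain integer codes")
            labels = rounded.astype(np.int32)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_map", dict(self.label_map))
        known = set(self.label_map.values()) | {0}
        present = set(np.unique(labels).tolist())
        orphan = present - known
        if orphan:
            raise ValueError(f"label codes {sorted(orphan)} missing from label_map")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of voxels belonging to ``region``.

        ``IVD`` is the union of the IVD, NP and AF codes; ``AF`` falls back
        to IVD-code voxels outside the NP when no AF code is mapped.
        """
        region = region.upper()
        if region == "IVD":
            codes = [self.label_map[r] for r in _IVD_PARTS if r in self.label_map]
            if not codes:
                raise EmptyRegionError("no IVD/NP/AF codes in label_map")
            return np.isin(self.labels, codes)
        if region == "AF" and "AF" not in self.label_map:
            if "IVD" not in self.label_map:
                raise EmptyRegionError("cannot derive AF: no AF or IVD code mapped")
            return self.labels == self.label_map["IVD"]
        if region not in self.label_map:
            raise EmptyRegionError(f"region {region!r} not in label_map")
        return self.labels == self.label_map[region]


@dataclass(frozen=True)
class RegionSample:
    """Per-region voxel sample: world positions, intensities, volume weights."""

    positions: np.ndarray  # (n, 3) mm
    intensities: np.ndarray  # (n,)
    weights: np.ndarray  # (n,), sums to 1
    region_name: str
    voxel_volume: float = 1.0  # mm^3 per voxel

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        inten = np.asarray(self.intensities, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        if not (len(pos) == len(inten) == len(w)):
            raise ValueError("positions, intensities and weights must have equal length")
        if len(inten) < 1:
            raise EmptyRegionError(f"region {self.region_name!r} is empty")
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.intensities)


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D NIfTI image as a :class:`VolumeGrid`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:  # tolerate trailing singleton
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {data.ndim}D")
    return VolumeGrid(data=np.asarray(data, dtype=np.float64), affine=np.asarray(img.affine))


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` to a NIfTI-1 file."""
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine), str(path))


def load_mask(path: str | Path, label_map: Mapping[str, int] | None = None) -> LabelMask:
    """Load an integer NIfTI label image as a :class:`LabelMask`."""
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim == 4 and labels.shape[3] == 1:
        labels = labels[..., 0]
    if labels.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D label image, got {labels.ndim}D")
    return LabelMask(labels=labels, label_map=label_map or dict(DEFAULT_LABEL_MAP))


def save_mask(mask: LabelMask, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), np.asarray(affine)), str(path))


def extract_region(
    volume: VolumeGrid,
    mask: LabelMask,
    region: str,
    *,
    units: str = "mm",
) -> RegionSample:
    """Extract the voxels of one labeled region as a :class:`RegionSample`.

    Parameters
    ----------
    units:
        ``"mm"`` maps voxel indices through the affine (default);
        ``"voxel"`` keeps raw 0-based voxel indices as positions.
    """
    if mask.labels.shape != volume.data.shape:
        raise AlignmentError(
            f"mask shape {mask.labels.shape} != volume shape {volume.data.shape}"
        )
    if units not in ("mm", "voxel"):
        raise ValueError(f"units must be 'mm' or 'voxel', got {units!r}")
    sel = mask.region_mask(region)
    n = int(sel.sum())
    if n == 0:
        raise EmptyRegionError(f"region {region!r} has no voxels in this mask")
    idx = np.argwhere(sel).astype(float)
    if units == "mm":
        positions = nib.affines.apply_affine(volume.affine, idx)
    else:
        positions = idx
    # Uniform grid: every voxel has the same physical volume, so the
    # volume-fraction weights are exactly 1/n each.
    weights = np.full(n, 1.0 / n)
    return RegionSample(
        positions=positions,
        intensities=volume.data[sel],
        weights=weights,
        region_name=region.upper(),
        voxel_volume=volume.voxel_volume,
    )
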