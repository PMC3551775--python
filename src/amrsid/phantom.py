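"""Synthetic T2-weighted disc phantoms.

A phantom emulates the structures the analysis pipeline consumes: an
ellipsoidal intervertebral disc (IVD) with a bright nucleus pulposus (NP)
core and a dark annulus fibrosus (AF) shell, plus two rectangular
reference-tissue blocks (CSF, very bright; cancellous bone, intermediate)
outside the disc.  Controls emulate the physics the method must be robust or
sensitive to:

* ``gain`` — a global multiplicative acquisition gain applied to every
  tissue, which reference normalization must cancel exactly;
* ``np_offset`` — a rigid displacement of the NP core inside the disc,
  which shifts the intensity-weighted center;
* ``degeneration`` in [0, 1] — mixes the NP intensity toward the AF value
  and Gaussian-blurs the NP/AF boundary, reproducing the histogram signature
  of disc degeneration (std and sum-of-squares rise, KS distance falls);
* ``noise_sd`` — additive Gaussian noise (a simplification of Rician
  magnitude noise, adequate at the simulated SNR).

Two structural features give the healthy disc a realistic, non-trivial
signal: a radial T2 attenuation toward the dry outer annulus
(``edge_drop``), anchored to the disc frame so that an off-center nucleus is
attenuated asymmetrically and the weighted center responds to displacement,
and a thin partial-volume transition rim at the NP/AF boundary
(``boundary_sigma``) whose bright mass a healthy annulus histogram carries
as a far, concentrated tail.  Degeneration widens that rim and fades the
nucleus, spreading the bright mass through the annulus: its histogram widens
(std, sum of squares rise) while becoming smoother and closer to its fitted
Gaussian (KS distance falls).

Default intensities put CSF at 1000, NP at 800, AF at 200 and bone at 320
arbitrary units, matching the qualitative T2 contrast of a lumbar spine
acquisition; the default control NP/IVD volume ratio is 27% (semi-axis
scale 0.27^(1/3)).  The default cohort reproduces the five-group study
layout: low/high severity scoliosis (n=16 each), low/high severity
spondylolisthesis (n=16 each) and controls (n=15) with group-specific NP
size and displacement distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContainmentError
from .volumes_io import DEFAULT_LABEL_MAP, LabelMask, VolumeGrid


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic disc volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    ivd_semi_axes: tuple[float, float, float] = (18.0, 14.0, 6.0)  # mm
    np_semi_axes: tuple[float, float, float] | None = None  # default: scale * ivd
    np_scale: float = 0.27 ** (1.0 / 3.0)  # NP/IVD semi-axis ratio -> 27% volume
    np_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    intensity_np: float = 800.0
    intensity_af: float = 200.0
    intensity_csf: float = 1000.0
    intensity_bone: float = 320.0
    degeneration: float = 0.0
    gain: float = 1.0
    noise_sd: float = 20.0
    edge_drop: float = 0.35  # fractional T2 loss at the outer annulus
    boundary_sigma: float = 0.7  # mm, healthy NP/AF partial-volume rim
    blur_per_degeneration: float = 1.5  # mm of extra boundary blur at deg=1
    np_fade: float = 0.2  # fraction of the NP->AF blend reached at deg=1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.degeneration <= 1.0:
            raise ValueError("degeneration must be in [0, 1]")
        for name in ("intensity_np", "intensity_af", "intensity_csf", "intensity_bone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.ivd_semi_axes) <= 0:
            raise ValueError("ivd_semi_axes must be positive")
        if self.np_semi_axes is not None and min(self.np_semi_axes) <= 0:
            raise ValueError("np_semi_axes must be positive")

    @property
    def np_axes(self) -> np.ndarray:
        if self.np_semi_axes is not None:
            return np.asarray(self.np_semi_axes, dtype=float)
        return self.np_scale * np.asarray(self.ivd_semi_axes, dtype=float)


def _check_np_inside_ivd(spec: PhantomSpec, n_dirs: int = 400) -> None:
    """Sampled surface check that the (offset) NP ellipsoid lies in the IVD."""
    rng = np.random.default_rng(12345)  # fixed: geometry check, not simulation
    u = rng.normal(size=(n_dirs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.asarray(spec.np_offset) + u * spec.np_axes
    ivd = np.asarray(spec.ivd_semi_axes)
    if np.any(np.sum((pts / ivd) ** 2, axis=1) > 1.0 + 1e-9):
        raise ContainmentError("NP ellipsoid (after offset) extends outside the IVD ellipsoid")


def _reference_blocks(shape: tuple[int, int, int]) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    """Corner cuboids for the CSF and bone reference samples."""
    nx, ny, nz = shape
    dx, dy, dz = max(nx // 10, 2), max(ny // 10, 2), max(nz // 3, 2)
    csf = (slice(1, 1 + dx), slice(1, 1 + dy), slice(1, 1 + dz))
    bone = (slice(nx - 1 - dx, nx - 1), slice(1, 1 + dy), slice(1, 1 + dz))
    return csf, bone


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, LabelMask]:
    """Voxelize one disc phantom; deterministic for a fixed spec (incl. seed)."""
    _check_np_inside_ivd(spec)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    affine = np.diag([*spacing, 1.0])

    center = (np.asarray(shape) - 1) / 2.0 * spacing  # disc at grid center, mm
    coords = np.stack(
        np.meshgrid(*(np.arange(s) * sp for s, sp in zip(shape, spacing)), indexing="ij"),
        axis=-1,
    )
    rel = coords - center
    ivd_in = np.sum((rel / np.asarray(spec.ivd_semi_axes)) ** 2, axis=-1) <= 1.0
    np_in = np.sum(((rel - np.asarray(spec.np_offset)) / spec.np_axes) ** 2, axis=-1) <= 1.0
    np_in &= ivd_in  # voxelization can clip corners; containment already checked
    af_in = ivd_in & ~np_in

    labels = np.zeros(shape, dtype=np.int16)
    labels[af_in] = DEFAULT_LABEL_MAP["AF"]
    labels[np_in] = DEFAULT_LABEL_MAP["NP"]
    csf_sl, bone_sl = _reference_blocks(shape)
    for sl, name in ((csf_sl, "CSF"), (bone_sl, "BONE")):
        block = np.zeros(shape, dtype=bool)
        block[sl] = True
        if np.any(block & ivd_in):
            raise ContainmentError("reference block overlaps the disc; enlarge the grid")
        labels[block] = DEFAULT_LABEL_MAP[name]

    # degeneration fades the NP toward the AF intensity (partial linear blend)
    np_intensity = spec.intensity_np + spec.np_fade * spec.degeneration * (
        spec.intensity_af - spec.intensity_np
    )
    tissue = np.zeros(shape, dtype=float)
    tissue[af_in] = spec.intensity_af
    tissue[np_in] = np_intensity
    # radial T2 attenuation toward the dry outer annulus, in the disc frame
    r_ivd = np.sqrt(np.sum((rel / np.asarray(spec.ivd_semi_axes)) ** 2, axis=-1))
    tissue[ivd_in] *= 1.0 - spec.edge_drop * np.clip(r_ivd[ivd_in], 0.0, 1.0) ** 2
    # NP/AF transition rim: thin for a healthy disc, widening with degeneration.
    # Normalized convolution restricted to the disc interior: the rim spreads
    # NP brightness into the annulus without bleeding in exterior signal.
    sigma_mm = spec.boundary_sigma + spec.blur_per_degeneration * spec.degeneration
    if sigma_mm > 0:
        interior = ivd_in.astype(float)
        sig = sigma_mm / spacing
        blurred = gaussian_filter(tissue * interior, sigma=sig)
        support = gaussian_filter(interior, sigma=sig)
        tissue[ivd_in] = blurred[ivd_in] / support[ivd_in]
    tissue[labels == DEFAULT_LABEL_MAP["CSF"]] = spec.intensity_csf
    tissue[labels == DEFAULT_LABEL_MAP["BONE"]] = spec.intensity_bone

    rng = np.random.default_rng(spec.seed)
    data = spec.gain * tissue + rng.normal(0.0, spec.noise_sd, size=shape)
    return VolumeGrid(data=data, affine=affine), LabelMask(labels=labels)


@dataclass(frozen=True)
class GroupParams:
    """Per-group parameter distributions (mean, sd) for cohort draws."""

    n: int
    np_scale: tuple[float, float] = (0.27 ** (1 / 3), 0.05)
    np_offset_mag: tuple[float, float] = (0.5, 0.3)  # mm, in-plane displacement
    degeneration: tuple[float, float] = (0.0, 0.0)
    gain: tuple[float, float] = (1.0, 0.1)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("group size must be >= 3")
        for f in ("np_scale", "np_offset_mag", "degeneration", "gain"):
            if getattr(self, f)[1] < 0:
                raise ValueError(f"{f} sd must be >= 0")


def _scale_for_ratio(ratio: float) -> float:
    return float(ratio) ** (1.0 / 3.0)


#: Study-layout defaults: five groups, NP/IVD volume-ratio distributions from
#: the clinical cohort (control 27.0+-6.3%, scoliosis 18.9+-3.4 / 19.9+-5.0%,
#: spondylolisthesis 22.2+-3.6 / 18.0+-4.8%), nucleus displacement larger in
#: scoliosis than control or spondylolisthesis, degeneration rising with
#: severity.
DEFAULT_GROUPS: dict[tuple[str, str], GroupParams] = {
    ("scoliosis", "low"): GroupParams(
        n=16, np_scale=(_scale_for_ratio(0.189), 0.020),
        np_offset_mag=(2.0, 0.8), degeneration=(0.25, 0.10),
    ),
    ("scoliosis", "high"): GroupParams(
        n=16, np_scale=(_scale_for_ratio(0.199), 0.029),
        np_offset_mag=(2.0, 0.8), degeneration=(0.45, 0.10),
    ),
    ("spondylolisthesis", "low"): GroupParams(
        n=16, np_scale=(_scale_for_ratio(0.222), 0.020),
        np_offset_mag=(0.7, 0.4), degeneration=(0.25, 0.10),
    ),
    ("spondylolisthesis", "high"): GroupParams(
        n=16, np_scale=(_scale_for_ratio(0.180), 0.029),
        np_offset_mag=(1.0, 0.5), degeneration=(0.45, 0.10),
    ),
    ("control", "none"): GroupParams(
        n=15, np_scale=(_scale_for_ratio(0.270), 0.026),
        np_offset_mag=(0.9, 0.5), degeneration=(0.05, 0.05),
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of phantoms: per-group parameter distributions + master seed."""

    groups: Mapping[tuple[str, str], GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    base: PhantomSpec = field(default_factory=PhantomSpec)
    master_seed: int = 0

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    group: str
    severity: str
    spec: PhantomSpec


def cohort_subject_specs(spec: CohortSpec) -> list[CohortSubject]:
    """Draw one PhantomSpec per subject, reproducibly from the master seed."""
    ss = np.random.SeedSequence(spec.master_seed)
    subjects: list[CohortSubject] = []
    ivd = np.asarray(spec.base.ivd_semi_axes)
    k = 0
    for (group, severity), params in spec.groups.items():
        child_seeds = ss.spawn(params.n)
        for j in range(params.n):
            rng = np.random.default_rng(child_seeds[j])
            scale = float(np.clip(rng.normal(*params.np_scale), 0.2, 0.95))
            mag = abs(rng.normal(*params.np_offset_mag))
            theta = rng.uniform(0, 2 * np.pi)  # displacement is in-plane
            offset = (mag * np.cos(theta), mag * np.sin(theta), 0.0)
            deg = float(np.clip(rng.normal(*params.degeneration), 0.0, 1.0))
            gain = max(float(rng.normal(*params.gain)), 0.1)
            # keep the displaced NP inside the disc
            max_mag = (1.0 - scale) * min(ivd[0], ivd[1]) * 0.95
            if mag > max_mag:
                shrink = max_mag / mag
                offset = tuple(o * shrink for o in offset)
            subj_seed = int(rng.integers(0, 2**31 - 1))
            subjects.append(
                CohortSubject(
                    subject_id=f"S{k:03d}",
                    group=group,
                    severity=severity,
                    spec=replace(
                        spec.base,
                        np_semi_axes=tuple(scale * ivd),
                        np_offset=offset,
                        degeneration=deg,
                        gain=gain,
                        seed=subj_seed,
                    ),
                )
            )
            k += 1
    return subjects


def generate_cohort(
    spec: CohortSpec,
) -> Iterator[tuple[CohortSubject, VolumeGrid, LabelMask]]:
    """Yield (subject, volume, mask) for every cohort member."""
    for subject in cohort_subject_specs(spec):
        volume, mask = generate_phantom(subject.spec)
        yield subject, volume, mask
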