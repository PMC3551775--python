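"""End-to-end per-disc analysis: images -> index rows -> cohort tables.

One disc yields, per (region in {IVD, NP, AF}) x (normalization in the
configured set), a row carrying the eight histogram indices plus the
weighted/geometric-center distance; the NP/IVD volume ratio is attached to
the NP rows (it involves two regions at once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmrsidError, EmptyRegionError
from .geometry_indices import center_distance, volume_ratio
from .histogram_indices import HistogramSpec, IndexSet, compute_index_set
from .normalization import identity_normalization, normalize_intensities, reference_mean
from .volumes_io import DEFAULT_LABEL_MAP, LabelMask, VolumeGrid, extract_region

logger = logging.getLogger(__name__)

ANALYSIS_REGIONS = ("IVD", "NP", "AF")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration shared by the CLI and the library entry points."""

    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    normalizations: Sequence[str] = ("csf", "bone")
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    units: str = "mm"  # coordinate units for center geometry: mm | voxel
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.normalizations:
            raise ValueError("at least one normalization must be configured")
        for nrm in self.normalizations:
            if nrm.lower() not in ("csf", "bone", "none"):
                raise ValueError(f"unknown normalization {nrm!r}")


def disc_indices(
    volume: VolumeGrid,
    mask: LabelMask,
    config: RunConfig | None = None,
    *,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """All indices for one disc: one row per region x normalization."""
    config = config or RunConfig()
    samples = {}
    for region in ANALYSIS_REGIONS:
        try:
            samples[region] = extract_region(volume, mask, region, units=config.units)
        except EmptyRegionError:
            logger.warning("%s: region %s empty, skipping", subject_id, region)
    if "IVD" not in samples:
        raise EmptyRegionError(f"{subject_id}: no disc voxels found")

    ref_means = {}
    for nrm in config.normalizations:
        kind = nrm.upper()
        if kind == "NONE":
            ref_means[kind] = 1.0
            continue
        ref_sample = extract_region(volume, mask, kind, units=config.units)
        ref_means[kind] = reference_mean(ref_sample)
        logger.info("%s: %s reference mean = %.4f", subject_id, kind, ref_means[kind])

    vr = None
    if "NP" in samples:
        vr = volume_ratio(samples["NP"], samples["IVD"])

    rows = []
    for region, sample in samples.items():
        for nrm in config.normalizations:
            kind = nrm.upper()
            if kind == "NONE":
                norm = identity_normalization(sample)
            else:
                norm = normalize_intensities(sample, ref_means[kind], reference_kind=kind)
            idx: IndexSet = compute_index_set(sample, norm, config.histogram)
            pair = center_distance(sample, norm.normalized_intensities)
            row = dict(
                subject_id=subject_id,
                region=region,
                normalization=kind,
                reference_mean=norm.reference_mean,
                n_voxels=sample.n,
                **idx.as_dict(),
                center_distance=pair.d,
                wx=pair.W[0], wy=pair.W[1], wz=pair.W[2],
                gx=pair.G[0], gy=pair.G[1], gz=pair.G[2],
            )
            row["volume_ratio"] = vr.ratio if (vr is not None and region == "NP") else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


#: Index columns carried from wide per-subject rows into the long cohort table.
INDEX_COLUMNS = list(IndexSet.FIELDS) + ["center_distance", "volume_ratio"]


def cohort_long_table(indices: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Join per-subject index rows with group assignments into the long format
    consumed by :func:`amrsid.group_stats.significance_report`.

    ``groups`` needs columns subject_id, group, severity.
    """
    for col in ("subject_id", "group", "severity"):
        if col not in groups.columns:
            raise ValueError(f"groups table missing column {col!r}")
    unknown = set(indices["subject_id"]) - set(groups["subject_id"])
    if unknown:
        raise AmrsidError(
            f"subjects missing from groups table: {sorted(unknown)[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    merged = indices.merge(groups[["subject_id", "group", "severity"]], on="subject_id")
    long = merged.melt(
        id_vars=["subject_id", "group", "severity", "region", "normalization"],
        value_vars=[c for c in INDEX_COLUMNS if c in merged.columns],
        var_name="index",
        value_name="value",
    )
    # volume_ratio is attached to NP rows only; drop its placeholder NaNs
    return long.dropna(subset=["value"]).reset_index(drop=True)
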