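"""First-order descriptive indices of the normalized intensity histogram.

Eight indices summarize the volume-weighted distribution of normalized T2
signal within a disc region: standard deviation, standard error, median,
sum of squared values, 75th percentile, maximal histogram-bin volume
fraction, skewness, and the Kolmogorov-Smirnov distance between the
weighted empirical CDF and the Gaussian fitted to the same data.

All indices use volume-fraction weights, so they estimate integrals over the
region and do not depend on voxel count (the standard error, sigma/sqrt(n),
is the one deliberate exception).  Degenerate zero-variance regions yield
NaN for skewness and the KS distance rather than a misleading 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateDistributionError
from .normalization import NormalizationResult
from .volumes_io import RegionSample


@dataclass(frozen=True)
class HistogramSpec:
    """Binning used only for the modal-bin index.

    bin_width is in normalized-intensity units (default 0.01); range=None
    auto-ranges from 0 to the sample maximum.
    """

    bin_width: float = 0.01
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.range is not None and self.range[1] <= self.range[0]:
            raise ValueError("histogram range must satisfy hi > lo")

    def edges(self, values: np.ndarray) -> np.ndarray:
        lo, hi = self.range if self.range is not None else (0.0, float(np.max(values)))
        hi = max(hi, lo + self.bin_width)
        nbins = int(np.ceil((hi - lo) / self.bin_width - 1e-12))
        return lo + self.bin_width * np.arange(nbins + 1)


@dataclass(frozen=True)
class IndexSet:
    """The eight histogram indices for one region of one subject."""

    std: float
    sem: float
    median: float
    sum_sq: float
    p75: float
    max_bin_weight: float
    skewness: float  # NaN when variance is 0
    ks_distance: float  # NaN when variance is 0

    #: CSV column order used throughout the pipeline.
    FIELDS = ("std", "sem", "median", "sum_sq", "p75", "max_bin_weight", "skewness", "ks_distance")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def _checked(values, weights):
    x = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if len(x) != len(w) or len(x) == 0:
        raise ValueError("values and weights must be non-empty and of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return x, w / s


def weighted_moments(values, weights) -> tuple[float, float, float]:
    """Volume-weighted mean, standard deviation and skewness.

    Population conventions: sigma = sqrt(sum w_i (x_i-mu)^2) and
    g1 = sum w_i (x_i-mu)^3 / sigma^3.  Skewness is NaN at zero variance.
    """
    x, w = _checked(values, weights)
    mu = float(np.sum(w * x))
    d = x - mu
    var = float(np.sum(w * d * d))
    sigma = np.sqrt(var)
    if sigma == 0.0:
        return mu, 0.0, float("nan")
    skew = float(np.sum(w * d**3) / sigma**3)
    return mu, float(sigma), skew


def weighted_quantile(values, weights, q: float) -> float:
    """Quantile of the weighted empirical distribution.

    Sorted values x_(i) with normalized weights w_(i) and cumulative sums c_i
    get plotting positions p_i = (c_i - w_i) / (1 - w_i); the quantile is
    linear interpolation of x against p.  For equal weights this reduces to
    p_i = (i-1)/(n-1), the standard linear-interpolated sample quantile, and
    q=0 / q=1 map to the minimum / maximum for any weights.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    x, w = _checked(values, weights)
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    if len(x) == 1:
        return float(x[0])
    c = np.cumsum(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (c - w) / (1.0 - w)
    p = np.where(w >= 1.0, 0.5, p)  # single-atom guard
    return float(np.interp(q, p, x))


def sum_of_squares(values, weights, *, weighted: bool = True) -> float:
    """Volume-weighted sum of squared intensities, sum w_i x_i^2.

    The unweighted plain sum (sum x_i^2, voxel-count dependent) is available
    with ``weighted=False``.
    """
    x, w = _checked(values, weights)
    if not weighted:
        return float(np.sum(x * x))
    return float(np.sum(w * x * x))


def max_bin_weight(values, weights, spec: HistogramSpec | None = None) -> float:
    """Largest volume fraction falling in a single histogram bin."""
    spec = spec or HistogramSpec()
    x, w = _checked(values, weights)
    edges = spec.edges(x)
    hist, _ = np.histogram(x, bins=edges, weights=w)
    # np.histogram drops values outside the range; include them via clipping
    # so the modal mass is computed over all voxels.
    if x.min() < edges[0] or x.max() > edges[-1]:
        hist, _ = np.histogram(np.clip(x, edges[0], edges[-1]), bins=edges, weights=w)
    return float(hist.max())


def ks_distance(values, weights) -> float:
    """Kolmogorov-Smirnov distance to the Gaussian fitted to the same data.

    sup_x |F_w(x) - Phi((x-mu)/sigma)| with F_w the weighted ECDF and mu,
    sigma the volume-weighted mean and (population) standard deviation.  The
    supremum over a piecewise-constant ECDF minus a continuous CDF is attained
    at a jump, so both sides of every step are checked.
    """
    x, w = _checked(values, weights)
    mu, sigma, _ = weighted_moments(x, w)
    if sigma == 0.0:
        raise DegenerateDistributionError("zero-variance region: KS distance undefined")
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    # collapse duplicate values into single ECDF steps
    ux, inv = np.unique(x, return_inverse=True)
    uw = np.bincount(inv, weights=w)
    cdf_after = np.cumsum(uw)
    cdf_before = cdf_after - uw
    gauss = norm.cdf((ux - mu) / sigma)
    d = max(np.max(np.abs(cdf_after - gauss)), np.max(np.abs(cdf_before - gauss)))
    return float(min(d, 1.0))


def standard_error(values, weights) -> float:
    """sigma / sqrt(n), with n the voxel count and sigma the weighted std."""
    x, w = _checked(values, weights)
    _, sigma, _ = weighted_moments(x, w)
    return float(sigma / np.sqrt(len(x)))


def compute_index_set(
    sample: RegionSample,
    norm: NormalizationResult,
    spec: HistogramSpec | None = None,
) -> IndexSet:
    """All eight indices of one region's normalized intensity histogram."""
    x = np.asarray(norm.normalized_intensities, dtype=float)
    w = sample.weights
    if len(x) != len(w):
        raise ValueError("normalization result does not match the region sample")
    _, sigma, skew = weighted_moments(x, w)
    try:
        ks = ks_distance(x, w)
    except DegenerateDistributionError:
        ks = float("nan")
    return IndexSet(
        std=sigma,
        sem=standard_error(x, w),
        median=weighted_quantile(x, w, 0.5),
        sum_sq=sum_of_squares(x, w),
        p75=weighted_quantile(x, w, 0.75),
        max_bin_weight=max_bin_weight(x, w, spec),
        skewness=skew,
        ks_distance=ks,
    )
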