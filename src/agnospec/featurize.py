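"""Histogram-image featurization of peak lists.

Each (sample, parity) peak list is condensed into a 32 x 32 x 5 tensor
indexed by (mass bin i, log-abundance bin j, KMD bin k):

1.  The abundance coordinate of a peak with intensity ``a`` is

        y = (ln a - <ln a> + 0.5) / 9.2

    where ``<ln a>`` is the mean natural-log intensity over the peaks of
    the spectrum being featurized.  Subtracting the mean makes the image
    invariant to an overall intensity scale; the offset 0.5 and scale
    9.2 place both the strongest peaks and the noise floor inside
    [0, 1].  Peaks with y outside [0, 1] are dropped (not clipped).

2.  Raw counts ``n_ijk`` are normalized across the mass axis for every
    fixed (j, k):

        N_ijk = n_ijk / (sum_i n_ijk + eps),    eps = 1e-8,

    so faint but structured columns are put on the same footing as
    densely populated ones.

3.  A truncated log transform compresses the dynamic range:

        X_ijk = 0.5 ln(0.1 + N_ijk) + 1.25,

    mapping [0, 1] into roughly [0.0987, 1.2977].

Natural logarithms are used throughout; bin edges are half-open
[lo, hi) with the final bin closed at the top, on all three axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peaklist import Spectrum, kendrick_arrays

__all__ = [
    "HistogramConfig",
    "FeatureImage",
    "abundance_coordinate",
    "bin_counts",
    "normalize_counts",
    "log_transform",
    "featurize_spectrum",
    "flatten",
]


@dataclass(frozen=True)
class HistogramConfig:
    """Binning ranges, bin counts and transform constants.

    Defaults give the standard 32 x 32 x 5 image over m/z 150-750 and
    KMD -500..500 mDa (five 200-mDa bins).
    """

    mz_range: tuple[float, float] = (150.0, 750.0)
    n_mz_bins: int = 32
    n_abund_bins: int = 32
    kmd_range_mDa: tuple[float, float] = (-500.0, 500.0)
    n_kmd_bins: int = 5
    abund_offset: float = 0.5
    abund_scale: float = 9.2
    eps: float = 1e-8
    log_floor: float = 0.1
    log_gain: float = 0.5
    log_shift: float = 1.25
    clip_abundance: bool = False  # clip y into [0, 1] instead of dropping

    def __post_init__(self) -> None:
        for n in (self.n_mz_bins, self.n_abund_bins, self.n_kmd_bins):
            if n < 1:
                raise ValueError("bin counts must be >= 1")
        for lo, hi in (self.mz_range, self.kmd_range_mDa):
            if not lo < hi:
                raise ValueError("ranges must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_mz_bins, self.n_abund_bins, self.n_kmd_bins)

    @property
    def n_features(self) -> int:
        return self.n_mz_bins * self.n_abund_bins * self.n_kmd_bins

    @property
    def mz_bin_width(self) -> float:
        return (self.mz_range[1] - self.mz_range[0]) / self.n_mz_bins

    @property
    def x_min(self) -> float:
        """Transform value of an empty bin (N = 0)."""
        return self.log_gain * math.log(self.log_floor) + self.log_shift

    @property
    def x_max(self) -> float:
        """Transform value at the maximum admissible N = 1."""
        return self.log_gain * math.log(self.log_floor + 1.0) + self.log_shift


@dataclass
class FeatureImage:
    """Counts and transformed tensors for one (sample, parity) point."""

    sample_id: str
    parity: str
    counts: np.ndarray
    values: np.ndarray
    n_peaks_used: int

    def __post_init__(self) -> None:
        if self.counts.shape != self.values.shape:
            raise ValueError("counts and values must share a shape")
        if int(self.counts.sum()) != self.n_peaks_used:
            raise ValueError("count tensor inconsistent with n_peaks_used")


def abundance_coordinate(
    intensity: float | np.ndarray,
    mean_log: float,
    cfg: HistogramConfig = HistogramConfig(),
) -> float | np.ndarray:
    """Dimensionless abundance coordinate y of a peak (see module docs)."""
    a = np.asarray(intensity, dtype=float)
    if np.any(a <= 0):
        raise ValueError("intensities must be positive")
    y = (np.log(a) - mean_log + cfg.abund_offset) / cfg.abund_scale
    return float(y) if np.isscalar(intensity) else y


def _bin_indices(values: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Half-open [lo, hi) bins, final bin closed; -1 for out of range."""
    idx = np.floor((values - lo) / ((hi - lo) / n)).astype(np.int64)
    idx[values == hi] = n - 1
    idx[(values < lo) | (values > hi)] = -1
    return idx


def bin_counts(s: Spectrum, cfg: HistogramConfig = HistogramConfig()) -> np.ndarray:
    """Raw 3D histogram n_ijk of one peak list.

    The mean log intensity is computed over the peaks of ``s`` itself
    (i.e., after any windowing, S/N filtering and parity split), so each
    data point is self-calibrated.  Peaks falling outside the mass or
    KMD ranges, or with abundance coordinate outside [0, 1], do not
    contribute.  An empty spectrum gives an all-zero tensor.
    """
    n = np.zeros(cfg.shape, dtype=np.int64)
    if len(s) == 0:
        return n
    mz = s.mz
    intensity = s.intensity
    mean_log = float(np.mean(np.log(intensity)))
    y = (np.log(intensity) - mean_log + cfg.abund_offset) / cfg.abund_scale
    if cfg.clip_abundance:
        y = np.clip(y, 0.0, 1.0)
    _, _, kmd = kendrick_arrays(mz)

    i = _bin_indices(mz, cfg.mz_range[0], cfg.mz_range[1], cfg.n_mz_bins)
    j = _bin_indices(y, 0.0, 1.0, cfg.n_abund_bins)
    k = _bin_indices(kmd, cfg.kmd_range_mDa[0], cfg.kmd_range_mDa[1], cfg.n_kmd_bins)
    keep = (i >= 0) & (j >= 0) & (k >= 0)
    np.add.at(n, (i[keep], j[keep], k[keep]), 1)
    return n


def normalize_counts(
    n_ijk: np.ndarray, cfg: HistogramConfig = HistogramConfig()
) -> np.ndarray:
    """Mass-axis normalization N_ijk = n_ijk / (sum_i n_ijk + eps).

    The sum runs over the mass index i for each fixed (abundance, KMD)
    column; eps keeps empty columns at zero instead of dividing by zero.
    """
    n_ijk = np.asarray(n_ijk, dtype=float)
    if n_ijk.shape != cfg.shape:
        raise ValueError(f"expected shape {cfg.shape}, got {n_ijk.shape}")
    return n_ijk / (n_ijk.sum(axis=0, keepdims=True) + cfg.eps)


def log_transform(
    N_ijk: np.ndarray, cfg: HistogramConfig = HistogramConfig()
) -> np.ndarray:
    """Truncated log transform X = log_gain * ln(log_floor + N) + log_shift."""
    N_ijk = np.asarray(N_ijk, dtype=float)
    if np.any(N_ijk < 0) or np.any(N_ijk > 1):
        raise ValueError("normalized histogram values must lie in [0, 1]")
    return cfg.log_gain * np.log(cfg.log_floor + N_ijk) + cfg.log_shift


def featurize_spectrum(
    s: Spectrum, cfg: HistogramConfig = HistogramConfig()
) -> FeatureImage:
    """Full pipeline for one (sample, parity) peak list.

    Deterministic: identical inputs give bit-identical images.
    """
    counts = bin_counts(s, cfg)
    values = log_transform(normalize_counts(counts, cfg), cfg)
    return FeatureImage(
        sample_id=s.sample_id,
        parity=s.parity,
        counts=counts,
        values=values,
        n_peaks_used=int(counts.sum()),
    )


def flatten(img: FeatureImage | np.ndarray) -> np.ndarray:
    """Flatten a feature image to a vector, mass-major order.

    Axis order is (mass, abundance, KMD) in C (row-major) layout: the
    KMD index varies fastest, the mass index slowest.  With the default
    configuration the result has length 5120 = 32 * 32 * 5.  The
    inverse is ``vector.reshape(cfg.shape)``.
    """
    tensor = img.values if isinstance(img, FeatureImage) else np.asarray(img)
    return np.ascontiguousarray(tensor).reshape(-1)
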