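"""Intratumoral heterogeneity (texture) features from the segmented lesion.

Two classical texture representations are computed on a gray-level-quantized
tumor:

* the normalized gray-level co-occurrence matrix (NGLCM), a symmetric joint
  probability of level pairs at unit voxel offset accumulated over the 13
  unique 3-D directions — source of the second-order features *uniformity*,
  *entropy* (bits), *dissimilarity*, *homogeneity* and *inverse difference
  moment*;
* the neighborhood gray-tone difference matrix (NGTDM) of Amadasun & King,
  the per-level sum of absolute differences between each voxel and the mean
  of its 26-neighborhood — source of the higher-order features *coarseness*,
  *contrast*, *busyness* and *complexity*.

Quantization is equal-width min–max binning within the tumor mask (default
64 bins), so every feature is invariant under monotone affine rescaling of
the SUV values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pet_quant import SuvVolume, TumorSegmentation

__all__ = [
    "QuantizedTumor",
    "Nglcm",
    "Ngtdm",
    "TextureFeatures",
    "quantize",
    "nglcm",
    "nglcm_features",
    "ngtdm",
    "ngtdm_features",
    "texture_features",
    "DIRECTIONS_3D",
]

#: guard added to the NGTDM weighted-difference sum before inversion, so a
#: perfectly homogeneous tumor has finite (capped) coarseness 1/EPS_COARSENESS
EPS_COARSENESS = 1e-6

#: the 13 unique direction vectors of the 26-neighborhood (antiparallel pairs
#: collapsed; both orderings are counted so the matrix is symmetric)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass(frozen=True)
class QuantizedTumor:
    """Integer gray levels (1..n_bins) on the tumor mask; 0 outside."""

    levels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    mask: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        lev = np.asarray(self.levels, dtype=np.int64)
        m = np.asarray(self.mask, dtype=bool)
        if lev.shape != m.shape:
            raise ValueError("levels and mask must be congruent")
        inside = lev[m]
        if inside.size == 0:
            raise ValueError("empty mask")
        if inside.min() < 1 or inside.max() > self.n_bins:
            raise ValueError("masked levels must lie in 1..n_bins")
        object.__setattr__(self, "levels", lev)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class Nglcm:
    """Normalized symmetric co-occurrence matrix (indices are levels - 1)."""

    p: np.ndarray
    n_directions: int
    distance_voxels: int
    n_pairs: int


@dataclass(frozen=True)
class Ngtdm:
    """Per-level absolute neighborhood-difference sums and occupancy."""

    s: np.ndarray          # length n_bins, index i-1 holds s(i)
    p_i: np.ndarray        # occurrence probability of each level
    n_valid_voxels: int


@dataclass(frozen=True)
class TextureFeatures:
    uniformity: float
    entropy_bits: float
    dissimilarity: float
    homogeneity: float
    inverse_difference_moment: float
    coarseness: float
    contrast: float | None
    busyness: float | None
    complexity: float | None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "uniformity": self.uniformity,
            "entropy_bits": self.entropy_bits,
            "dissimilarity": self.dissimilarity,
            "homogeneity": self.homogeneity,
            "inverse_difference_moment": self.inverse_difference_moment,
            "coarseness": self.coarseness,
            "contrast": self.contrast,
            "busyness": self.busyness,
            "complexity": self.complexity,
        }


def quantize(
    volume: SuvVolume | np.ndarray,
    seg: TumorSegmentation | np.ndarray,
    n_bins: int = 64,
) -> QuantizedTumor:
    """Equal-width quantization of tumor SUVs into ``n_bins`` levels.

    Bin edges span [min, max] SUV within the mask; the top bin is
    right-closed so the maximum-SUV voxel gets level ``n_bins``.  A constant
    tumor degenerates to a single occupied level 1 with ``degenerate=True``.
    """
    values = volume.values if isinstance(volume, SuvVolume) else np.asarray(volume, float)
    mask = seg.mask if isinstance(seg, TumorSegmentation) else np.asarray(seg, bool)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not mask.any():
        raise ValueError("empty mask")

    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        edges = np.array([lo, hi])
        return QuantizedTumor(levels, n_bins, edges, mask, degenerate=True)

    edges = np.linspace(lo, hi, n_bins + 1)
    # right-open bins except the last, which is right-closed
    lev = np.floor((inside - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    lev[lev > n_bins] = n_bins
    levels[mask] = lev
    return QuantizedTumor(levels, n_bins, edges, mask, degenerate=False)


def nglcm(q: QuantizedTumor, distance: int = 1) -> Nglcm:
    """Symmetric co-occurrence matrix over the 13 unique 3-D directions.

    Counts are accumulated in both orderings for every direction (hence the
    symmetry), pairs with either voxel outside the mask are skipped, and the
    matrix is normalized to sum to one after pooling all directions.
    """
    if distance < 1:
        raise ValueError("distance must be a positive integer")
    nb = q.n_bins
    counts = np.zeros((nb, nb), dtype=np.int64)
    lev, mask = q.levels, q.mask
    shape = lev.shape

    for d in DIRECTIONS_3D:
        off = tuple(distance * c for c in d)
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        both = mask[src] & mask[dst]
        if not both.any():
            continue
        a = lev[src][both] - 1
        b = lev[dst][both] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)

    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid voxel pairs at the requested offset")
    return Nglcm(p=counts / total, n_directions=len(DIRECTIONS_3D),
                 distance_voxels=distance, n_pairs=total)


def nglcm_features(m: Nglcm) -> dict[str, float]:
    """Second-order features from the normalized co-occurrence matrix."""
    p = m.p
    nb = p.shape[0]
    i, j = np.meshgrid(np.arange(1, nb + 1), np.arange(1, nb + 1), indexing="ij")
    absdiff = np.abs(i - j)
    nz = p > 0
    return {
        "uniformity": float(np.sum(p * p)),
        "entropy_bits": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "dissimilarity": float(np.sum(p * absdiff)),
        "homogeneity": float(np.sum(p / (1.0 + absdiff))),
        "inverse_difference_moment": float(np.sum(p / (1.0 + (i - j) ** 2))),
    }


def ngtdm(q: QuantizedTumor) -> Ngtdm:
    """Neighborhood gray-tone difference table.

    For each masked voxel having at least one masked 26-neighbor, the
    neighborhood mean excludes the center and all out-of-mask voxels;
    ``s(i)`` accumulates |i - mean| over contributing voxels at level i and
    ``p_i`` is the fraction of contributing voxels at that level.
    """
    lev, mask = q.levels, q.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = np.where(mask, lev, 0).astype(float)
    nbr_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0.5)
    if not valid.any():
        raise ValueError("no masked voxel has any masked neighbor")

    nbr_mean = np.zeros_like(nbr_sum)
    nbr_mean[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(lev[valid] - nbr_mean[valid])
    levels_valid = lev[valid]

    nb = q.n_bins
    s = np.zeros(nb)
    np.add.at(s, levels_valid - 1, diff)
    counts = np.bincount(levels_valid - 1, minlength=nb).astype(float)
    n = int(valid.sum())
    return Ngtdm(s=s, p_i=counts / n, n_valid_voxels=n)


def ngtdm_features(t: Ngtdm) -> dict[str, float | None]:
    """Amadasun–King coarseness, contrast, busyness and complexity.

    Contrast and busyness need at least two occupied gray levels; for a
    single occupied level they are returned as ``None`` (explicitly
    undefined), never silently zero.  Coarseness for a perfectly homogeneous
    tumor is capped at ``1/EPS_COARSENESS``.
    """
    occupied = np.flatnonzero(t.p_i > 0)
    n_g = occupied.size
    n = t.n_valid_voxels
    p = t.p_i
    s = t.s
    ivals = occupied + 1  # gray levels are 1-based

    coarseness = 1.0 / (EPS_COARSENESS + float(np.sum(p * s)))

    if n_g < 2:
        return {"coarseness": coarseness, "contrast": None,
                "busyness": None, "complexity": None}

    pi = p[occupied]
    si = s[occupied]
    di = ivals[:, None] - ivals[None, :]

    contrast = (
        float(np.sum(pi[:, None] * pi[None, :] * di**2)) / (n_g * (n_g - 1))
    ) * (float(np.sum(s)) / n)

    ipi = ivals * pi
    denom = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    busyness = float(np.sum(pi * si)) / denom if denom > 0 else None

    psum = pi[:, None] + pi[None, :]
    num = np.abs(di) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
    complexity = float(np.sum(num / psum)) / n

    return {"coarseness": coarseness, "contrast": contrast,
            "busyness": busyness, "complexity": complexity}


def texture_features(
    volume: SuvVolume | np.ndarray,
    seg: TumorSegmentation | np.ndarray,
    n_bins: int = 64,
    distance: int = 1,
) -> TextureFeatures:
    """Convenience wrapper: quantize then compute all nine features."""
    q = quantize(volume, seg, n_bins=n_bins)
    second = nglcm_features(nglcm(q, distance=distance))
    higher = ngtdm_features(ngtdm(q))
    return TextureFeatures(
        **second,
        **higher,
        meta={
            "n_bins": n_bins,
            "distance_voxels": distance,
            "n_directions": len(DIRECTIONS_3D),
            "degenerate_quantization": q.degenerate,
            "coarseness_eps": EPS_COARSENESS,
        },
    )
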