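"""Fixed-threshold PET tumor segmentation and metabolic indices.

The lesion is delineated inside an operator-drawn seed region by keeping
voxels with SUV at or above a fixed threshold (default 2.5, the head-and-neck
convention) and retaining the largest 26-connected component.  From the
resulting mask three standard metabolic indices are computed:

* ``SUVmax`` — maximum standardized uptake value over the lesion;
* ``MTV``   — metabolic tumor volume, voxel count times voxel volume (mL);
* ``TLG``   — total lesion glycolysis, ``MTV × SUVmean`` (g/mL × mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SuvVolume",
    "TumorSegmentation",
    "MetabolicIndices",
    "NoAvidLesionError",
    "segment_fixed_threshold",
    "metabolic_indices",
    "load_suv_volume",
    "save_volume",
]

#: default SUV cutoff for tumor delineation
DEFAULT_SUV_THRESHOLD = 2.5

#: full 3-D connectivity (26 neighbors)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class NoAvidLesionError(ValueError):
    """Raised when no voxel inside the seed region reaches the SUV threshold."""


@dataclass(frozen=True)
class SuvVolume:
    """A volumetric SUV image with physical voxel spacing.

    Values are body-weight-normalized SUV, taken as given: no dose/weight
    recomputation is performed.
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    frame_of_reference: str = "synthetic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("SUV values must be finite")
        sp = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("voxel spacing must be three positive reals")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_spacing_mm", sp)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0


@dataclass(frozen=True)
class TumorSegmentation:
    """Boolean lesion mask plus the provenance of how it was obtained."""

    mask: np.ndarray
    threshold_suv: float
    seed_roi: np.ndarray
    n_voxels: int
    touches_boundary: bool = False
    connectivity: int = 26

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        r = np.asarray(self.seed_roi, dtype=bool)
        if m.shape != r.shape:
            raise ValueError("mask and seed_roi must be congruent")
        if np.any(m & ~r):
            raise ValueError("mask must be contained in seed_roi")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "seed_roi", r)
        object.__setattr__(self, "n_voxels", int(m.sum()))


@dataclass(frozen=True)
class MetabolicIndices:
    suvmax: float
    mtv_ml: float
    suvmean: float
    tlg: float
    provenance: dict = field(default_factory=dict)


def segment_fixed_threshold(
    volume: SuvVolume,
    seed_roi: np.ndarray,
    threshold: float = DEFAULT_SUV_THRESHOLD,
) -> TumorSegmentation:
    """Segment the primary lesion by fixed SUV threshold inside a seed ROI.

    The candidate set is ``{voxel in seed_roi : SUV >= threshold}``; the mask
    returned is its largest 26-connected component (the primary lesion is
    assumed to be a single connected structure).  An empty candidate set is an
    explicit :class:`NoAvidLesionError`, never an empty mask.
    """
    roi = np.asarray(seed_roi, dtype=bool)
    if roi.shape != volume.values.shape:
        raise ValueError("seed_roi shape does not match volume")
    if not roi.any():
        raise ValueError("seed_roi is empty")

    candidate = roi & (volume.values >= threshold)
    if not candidate.any():
        raise NoAvidLesionError(
            f"no avid lesion: no voxel inside seed_roi has SUV >= {threshold}"
        )

    labels, n_comp = ndimage.label(candidate, structure=_CONN26)
    if n_comp > 1:
        sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    else:
        mask = candidate

    # warn (via provenance flag) when the operator ROI touches the grid edge
    edge = np.zeros_like(roi)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    touches = bool((roi & edge).any())

    return TumorSegmentation(
        mask=mask,
        threshold_suv=float(threshold),
        seed_roi=roi,
        n_voxels=int(mask.sum()),
        touches_boundary=touches,
    )


def metabolic_indices(volume: SuvVolume, seg: TumorSegmentation) -> MetabolicIndices:
    """Compute SUVmax, MTV (mL), SUVmean and TLG over the segmented lesion."""
    if seg.mask.shape != volume.values.shape:
        raise ValueError("segmentation not congruent with volume")
    if seg.n_voxels == 0:
        raise ValueError("empty segmentation mask")

    suv = volume.values[seg.mask]
    suvmax = float(suv.max())
    suvmean = float(suv.mean())
    mtv_ml = seg.n_voxels * volume.voxel_volume_ml
    tlg = mtv_ml * suvmean
    return MetabolicIndices(
        suvmax=suvmax,
        mtv_ml=mtv_ml,
        suvmean=suvmean,
        tlg=tlg,
        provenance={
            "threshold_suv": seg.threshold_suv,
            "connectivity": seg.connectivity,
            "n_voxels": seg.n_voxels,
            "roi_touches_boundary": seg.touches_boundary,
        },
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_suv_volume(path) -> SuvVolume:
    """Read a 3-D NIfTI image as an :class:`SuvVolume` (spacing from header)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return SuvVolume(values=data, voxel_spacing_mm=tuple(float(z) for z in zooms),
                     frame_of_reference=str(path))


def save_volume(path, values: np.ndarray, voxel_spacing_mm) -> None:
    """Write an array (bool masks are cast to uint8) as NIfTI with spacing."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag(list(voxel_spacing_mm)[:3] + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
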