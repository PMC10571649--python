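"""2-D caliper diameters and 3-D volume from binary segmentation masks.

A lesion mask is a binary 3-D grid (slice x row x column) with per-axis
voxel spacing in mm.  The longest axial diameter (LD) of a lesion is the
maximum voxel-center-to-voxel-center Euclidean distance within any single
axial slice; the perpendicular diameter is the extent of that slice's
mask projected onto the normal of the LD segment.  Volume is the voxel
count times the voxel volume.

Distances are measured centre-to-centre, which underestimates an
edge-to-edge caliper by at most one in-plane pixel; the trade is
reproducibility.  The axial plane is the first array axis: readers must
reorient volumes so that axis 0 stacks axial slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "LabeledMaskVolume",
    "DiameterMeasurement",
    "VolumeMeasurement",
    "EmptyMaskError",
    "longest_axial_diameter",
    "lesion_volume",
    "is_measurable",
    "load_mask",
]

# slices with at most this many foreground voxels are measured by brute
# force; larger slices go through the convex hull first
_HULL_THRESHOLD = 50


class EmptyMaskError(ValueError):
    """Raised when a diameter is requested from a mask with no lesion voxels."""


@dataclass(frozen=True)
class LabeledMaskVolume:
    """Binary lesion mask with voxel spacing.

    ``voxels`` has axis order (slice, row, column); ``spacing`` is
    (slice thickness, row spacing, column spacing) in mm.  ``label``
    records what was segmented: the contrast-enhancing core or the
    FLAIR-hyperintense edema (which by convention includes the core).
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    label: str = "core"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError("mask must be a 3-D array (slice, row, column)")
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("mask voxels must contain only 0 and 1")
        object.__setattr__(self, "voxels", vox.astype(np.uint8, copy=False))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive values (mm)")
        object.__setattr__(self, "spacing", spacing)
        if self.label not in ("core", "edema"):
            raise ValueError("label must be 'core' or 'edema'")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass(frozen=True)
class DiameterMeasurement:
    """Longest axial diameter and same-slice perpendicular diameter (mm)."""

    ld_mm: float
    perp_mm: float
    slice_index: int
    endpoints: Tuple[Tuple[float, float], Tuple[float, float]]

    def __post_init__(self) -> None:
        if not (self.ld_mm >= self.perp_mm >= 0):
            raise ValueError("require ld_mm >= perp_mm >= 0")

    def is_measurable(self, min_ld_mm: float = 10.0,
                      min_perp_mm: float = 5.0) -> bool:
        return is_measurable(self.ld_mm, self.perp_mm,
                             min_ld_mm=min_ld_mm, min_perp_mm=min_perp_mm)


@dataclass(frozen=True)
class VolumeMeasurement:
    """Mask volume: voxel count times voxel volume, in cm^3."""

    volume_cm3: float
    voxel_count: int


def _max_pair_bruteforce(pts: np.ndarray):
    """Exact maximum pairwise distance with deterministic tie-breaking.

    Among all pairs attaining the maximum squared distance, the pair
    whose sorted endpoint coordinates are lexicographically smallest is
    returned.  ``pts`` is (n, 2) in mm.
    """
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(d2 == best)
    candidates = []
    for i, j in zip(ii, jj):
        if i < j:
            a, b = tuple(pts[i]), tuple(pts[j])
            candidates.append(tuple(sorted((a, b))))
    if not candidates:  # single point
        p = tuple(pts[0])
        return 0.0, (p, p)
    pair = min(candidates)
    return float(np.sqrt(best)), pair


def _max_pair(pts: np.ndarray):
    """Maximum pairwise distance; convex-hull accelerated for big slices.

    The diameter endpoints of a planar point set are hull vertices, so
    restricting the all-pairs search to hull vertices is exact (ties at
    the maximum never involve interior or mid-edge points because the
    squared distance along an edge is strictly convex).
    """
    if len(pts) <= _HULL_THRESHOLD:
        return _max_pair_bruteforce(pts)
    try:
        hull = ConvexHull(pts)
        return _max_pair_bruteforce(pts[hull.vertices])
    except QhullError:
        # degenerate (collinear) slice
        return _max_pair_bruteforce(np.unique(pts, axis=0))


def longest_axial_diameter(mask: LabeledMaskVolume) -> DiameterMeasurement:
    """Longest in-plane diameter over all axial slices, with perpendicular.

    Returns the maximum centre-to-centre distance between mask voxels
    within any single slice, in mm under the in-plane spacing, together
    with the width of that slice's mask projected on the LD normal.
    Ties across slices go to the lowest slice index, then to the
    lexicographically smallest endpoint pair.

    Raises
    ------
    EmptyMaskError
        If the mask contains no lesion voxels.
    """
    vox = mask.voxels
    if not vox.any():
        raise EmptyMaskError("no lesion voxels")
    _, sr, sc = mask.spacing
    scale = np.array([sr, sc])

    best_d = -1.0
    best_slice = -1
    best_pair = None
    best_pts = None
    for s in np.flatnonzero(vox.any(axis=(1, 2))):
        pts = np.argwhere(vox[s]).astype(float) * scale
        d, pair = _max_pair(pts)
        if d > best_d:
            best_d, best_slice, best_pair, best_pts = d, int(s), pair, pts

    if best_d == 0.0:
        warnings.warn("sub-voxel lesion: mask too small for a 2-D diameter",
                      stacklevel=2)
        perp = 0.0
    else:
        p1 = np.asarray(best_pair[0])
        p2 = np.asarray(best_pair[1])
        axis = p2 - p1
        normal = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
        proj = best_pts @ normal
        # the width along any direction cannot exceed the diameter; clamp
        # the float rounding that occurs when the two are equal
        perp = min(float(proj.max() - proj.min()), float(best_d))
    return DiameterMeasurement(ld_mm=float(best_d), perp_mm=perp,
                               slice_index=best_slice, endpoints=best_pair)


def lesion_volume(mask: LabeledMaskVolume) -> VolumeMeasurement:
    """Mask volume in cm^3: voxel count x voxel volume / 1000.  Empty masks
    are allowed and measure 0."""
    count = int(mask.voxels.sum())
    return VolumeMeasurement(volume_cm3=count * mask.voxel_volume_mm3 / 1000.0,
                             voxel_count=count)


def is_measurable(ld_mm: float, perp_mm: float, *,
                  min_ld_mm: float = 10.0, min_perp_mm: float = 5.0) -> bool:
    """Measurability predicate: LD and perpendicular at or above their
    thresholds (10 mm and 5 mm by default, both inclusive)."""
    return ld_mm >= min_ld_mm and perp_mm >= min_perp_mm


def load_mask(path, label: str = "core") -> LabeledMaskVolume:
    """Read a binary mask from a NIfTI file.

    Assumes axial slices are stacked along the last (third) data axis,
    the usual convention; the array is transposed to the package's
    (slice, row, column) order and spacing is taken from the header
    zooms.  Any voxel above 0.5 is foreground.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    vox = (np.transpose(data, (2, 1, 0)) > 0.5).astype(np.uint8)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return LabeledMaskVolume(voxels=vox, spacing=spacing, label=label)


def save_mask(mask: LabeledMaskVolume, path) -> None:
    """Write a mask to NIfTI, inverting the axis convention of ``load_mask``."""
    import nibabel as nib

    data = np.transpose(mask.voxels, (2, 1, 0)).astype(np.uint8)
    affine = np.diag([mask.spacing[2], mask.spacing[1], mask.spacing[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, str(path))
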