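"""Bone-volume-ratio ROI analysis of HU images.

Replicates the micro-CT morphometry around the implant: a hollow-cylinder
ROI hugging the bone-implant interface (V1/V0) is compared with equal-volume
spherical ROIs placed in far trabecular regions (V2/V0), with bone voxels
classified by HU-band thresholding and a classical paired t-test across
specimens.  A density-to-HU projection closes the loop between the remodeled
FE density field and the same image-based analysis applied to scans.

All ROI geometry uses voxel-center membership with half-open radial
intervals, so adjacent shells never double-count a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .materials import CalibrationConstants, density_to_hu
from .microct import HUImage, DEFAULT_HU_BONE, DEFAULT_HU_BACKGROUND
from . import fem

__all__ = [
    "ROIMask",
    "BVRResult",
    "PairedComparison",
    "hollow_cylinder_mask",
    "equal_volume_sphere_mask",
    "bone_volume_ratio",
    "paired_comparison",
    "density_to_hu_projection",
]


@dataclass(frozen=True)
class ROIMask:
    """Boolean voxel mask aligned to an HUImage, with its physical volume V0."""

    mask: np.ndarray
    shape_tag: str
    params: dict
    voxel_size: float

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty ROI mask")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """V0 in mm^3 (2D masks carry a 1 mm thickness)."""
        return self.n_voxels * self.voxel_size ** self.mask.ndim


@dataclass(frozen=True)
class BVRResult:
    v_bone: float  # mm^3
    v0: float  # mm^3
    ratio: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("bone volume ratio must lie in [0, 1]")


def _coord_grids(image: HUImage):
    coords = [image.voxel_centers(a) for a in range(image.ndim)]
    return np.meshgrid(*coords, indexing="ij")


def hollow_cylinder_mask(image: HUImage, center, inner_radius: float = 4.0,
                         thickness: float = 2.0, height: float = 10.0,
                         axis: int = -1) -> ROIMask:
    """Hollow cylinder ROI adjacent to the implant interface.

    ``inner_radius <= r < inner_radius + thickness`` around the given axis
    point; in 3D the height band extends down from the top face (the drilled
    side), mirroring the defect depth.  2D images use the annulus only.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive (empty ROI)")
    grids = _coord_grids(image)
    ndim = image.ndim
    ax = axis % ndim if ndim == 3 else None
    plane = [a for a in range(ndim) if a != ax] if ndim == 3 else [0, 1]
    dx = grids[plane[0]] - center[0]
    dy = grids[plane[1]] - center[1]
    r = np.sqrt(dx * dx + dy * dy)
    mask = (r >= inner_radius) & (r < inner_radius + thickness)
    if ndim == 3:
        z = grids[ax]
        z_top = image.origin[ax] + image.shape[ax] * image.voxel_size
        mask &= z >= z_top - height
    return ROIMask(mask, "hollow_cylinder",
                   {"center": tuple(center), "inner_radius": inner_radius,
                    "thickness": thickness, "height": height},
                   image.voxel_size)


def equal_volume_sphere_mask(image: HUImage, center, v0: float) -> ROIMask:
    """Spherical ROI (disc in 2D) whose volume matches a reference V0 (mm^3).

    The radius follows from the closed form ``(3 V0 / 4 pi)^(1/3)`` (or
    ``sqrt(V0 / pi)`` per unit thickness in 2D); the sphere must fit inside
    the image.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    ndim = image.ndim
    if ndim == 3:
        radius = (3.0 * v0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    else:
        radius = np.sqrt(v0 / np.pi)
    for a in range(ndim):
        lo = image.origin[a]
        hi = image.origin[a] + image.shape[a] * image.voxel_size
        if center[a] - radius < lo - image.voxel_size / 2 or center[a] + radius > hi + image.voxel_size / 2:
            raise ValueError("sphere of the requested volume does not fit in the image")
    grids = _coord_grids(image)
    r2 = sum((grids[a] - center[a]) ** 2 for a in range(ndim))
    mask = r2 <= radius * radius
    return ROIMask(mask, "sphere", {"center": tuple(center), "v0": v0, "radius": radius},
                   image.voxel_size)


def bone_volume_ratio(image: HUImage, roi: ROIMask, hu_band=None, label: str = "") -> BVRResult:
    """Fraction of ROI voxels whose HU lies in the bone band."""
    if hu_band is None:
        hu_band = image.hu_bone
    lo, hi = hu_band
    if not lo < hi:
        raise ValueError("hu_band must be an increasing interval")
    if roi.mask.shape != image.shape:
        raise ValueError("ROI mask does not align with the image")
    vals = image.values[roi.mask]
    n_bone = int(np.sum((vals >= lo) & (vals <= hi)))
    vox_vol = image.voxel_size ** image.ndim
    return BVRResult(v_bone=n_bone * vox_vol, v0=roi.volume,
                     ratio=n_bone / roi.n_voxels, label=label)


@dataclass(frozen=True)
class PairedComparison:
    mean_interface: float
    sd_interface: float
    mean_far: float
    sd_far: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False  # zero-variance differences with nonzero mean


def paired_comparison(interface_ratios, far_ratios) -> PairedComparison:
    """Classical paired t-test on interface vs far-field bone volume ratios.

    t = mean(d) / (sd(d) / sqrt(n)) on the paired differences, with the
    two-sided p from the t distribution with n - 1 degrees of freedom.
    Identical lists give t = 0, p = 1; zero-variance differences with a
    nonzero mean are reported as p -> 0 with a degeneracy flag.
    """
    a = np.asarray(interface_ratios, dtype=float)
    b = np.asarray(far_ratios, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired lists must be 1D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = a - b
    sd_d = float(np.std(d, ddof=1))
    mean_d = float(d.mean())
    degenerate = False
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, pval = 0.0, 1.0
        else:
            t = np.inf if mean_d > 0 else -np.inf
            pval = 0.0
            degenerate = True
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        pval = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedComparison(
        mean_interface=float(a.mean()), sd_interface=float(np.std(a, ddof=1)),
        mean_far=float(b.mean()), sd_far=float(np.std(b, ddof=1)),
        t_statistic=float(t), p_value=float(pval), n=n, degenerate=degenerate,
    )


def density_to_hu_projection(mat, mesh: fem.VoxelMesh,
                             cal: CalibrationConstants = CalibrationConstants(),
                             hu_bone=DEFAULT_HU_BONE,
                             hu_background=DEFAULT_HU_BACKGROUND) -> HUImage:
    """Project a (remodeled) per-element density field to a synthetic HU image.

    Inverts the affine HU->density calibration elementwise on bone elements;
    anchor and excluded voxels read as background, so the projected image can
    be fed to the same ROI / thresholding pipeline as a scan.
    """
    hu = np.asarray(density_to_hu(mat.density, cal), dtype=float)
    hu[mesh.region != fem.REGION_BONE] = hu_background
    grid = mesh.element_field_to_grid(hu, fill=hu_background)
    # element-centered image: voxel centers coincide with element centroids
    origin = tuple(c + 0.0 for c in mesh.origin)
    return HUImage(grid, voxel_size=mesh.voxel_size, origin=origin,
                   hu_bone=hu_bone, hu_background=hu_background)
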