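"""Synthetic trabecular micro-CT generation and the surgical defect model.

Generates reproducible voxel images of Hounsfield units (HU) that emulate
trabecular bone scanned by micro-CT: a smooth Gaussian random field is
thresholded at the empirical quantile that yields a prescribed bone volume
ratio, and HU values inside the bone phase ramp up with distance from the
marrow phase so that strut cores read denser than strut surfaces.  A
cylindrical surgical defect can then be drilled into the image and a
coaxial cylindrical anchor inserted (press-fit when the anchor diameter
equals the drill diameter).

Coordinates are 0-based voxel indices with axis order (x, y[, z]); the
physical position of a voxel center is ``origin + (index + 0.5) * voxel_size``.
Cylinder membership is evaluated at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "HUImage",
    "DefectSpec",
    "REGION_MARROW",
    "REGION_BONE",
    "REGION_ANCHOR",
    "REGION_VOID",
    "generate_trabecular_image",
    "drill_and_insert",
    "hu_histogram",
    "write_hu_image",
    "read_hu_image",
]

# region labels used throughout the pipeline
REGION_MARROW = 0
REGION_BONE = 1
REGION_ANCHOR = 2
REGION_VOID = 3

DEFAULT_HU_BONE = (200.0, 1000.0)
DEFAULT_HU_BACKGROUND = 0.0


@dataclass(frozen=True)
class HUImage:
    """A voxel grid of Hounsfield units with isotropic voxel size (mm)."""

    values: np.ndarray
    voxel_size: float
    origin: tuple = None
    hu_bone: tuple = DEFAULT_HU_BONE
    hu_background: float = DEFAULT_HU_BACKGROUND

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim not in (2, 3):
            raise ValueError("HUImage requires a 2D or 3D grid")
        if min(values.shape) < 1:
            raise ValueError("all image dimensions must be >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(values)):
            raise ValueError("HU values must be finite")
        object.__setattr__(self, "values", values)
        origin = self.origin
        if origin is None:
            origin = (0.0,) * values.ndim
        if len(origin) != values.ndim:
            raise ValueError("origin must have one entry per image axis")
        object.__setattr__(self, "origin", tuple(float(c) for c in origin))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def bone_mask(self) -> np.ndarray:
        lo, hi = self.hu_bone
        return (self.values >= lo) & (self.values <= hi)

    def bone_volume_fraction(self) -> float:
        return float(self.bone_mask().mean())


@dataclass(frozen=True)
class DefectSpec:
    """Cylindrical drill defect with a coaxial cylindrical anchor.

    The axis is aligned with one grid axis; ``center`` gives the in-plane
    physical coordinates (mm) of the cylinder axis.  In 3D the defect is
    drilled from the top face (maximum coordinate along ``axis``) down to
    ``depth``; in 2D the image is a transverse section and ``depth`` is
    ignored.
    """

    center: tuple
    diameter: float
    depth: float
    anchor_diameter: float = None
    axis: int = -1  # grid axis index of the cylinder axis (3D only)

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not self.depth > 0:
            raise ValueError("depth must be positive")
        anchor = self.anchor_diameter
        if anchor is None:
            anchor = self.diameter  # press-fit: anchor fills the drill hole
        if anchor > self.diameter:
            raise ValueError("anchor_diameter must not exceed the drill diameter")
        object.__setattr__(self, "anchor_diameter", float(anchor))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def generate_trabecular_image(
    shape,
    voxel_size: float = 0.25,
    target_bvr: float = 0.47,
    correlation_length: float = 0.6,
    hu_bone: tuple = DEFAULT_HU_BONE,
    hu_background: float = DEFAULT_HU_BACKGROUND,
    seed: int = 0,
    ramp_scale: float = 3.0,
) -> HUImage:
    """Generate a synthetic trabecular HU image with a controlled bone volume ratio.

    A standard-normal white-noise field is smoothed with an isotropic Gaussian
    kernel of width ``correlation_length`` (mm) and thresholded at the
    empirical ``1 - target_bvr`` quantile, so the realized bone-voxel fraction
    matches ``target_bvr`` up to ties.  Bone voxels receive HU values on a
    linear ramp with Euclidean distance from the marrow phase, clipped to the
    ``hu_bone`` band; marrow voxels receive ``hu_background``.  The ramp
    reaches the top of the band at ``ramp_scale`` correlation lengths, so only
    the thickest strut cores saturate and the HU histogram stays spread over
    the band (which is what makes the discrete material-type binning
    nontrivial).

    Identical ``seed`` (with identical arguments) yields a bit-identical image.
    """
    shape = tuple(int(n) for n in np.atleast_1d(shape))
    if len(shape) == 1:
        shape = shape * 3
    if any(n <= 0 for n in shape):
        raise ValueError("image shape entries must be positive")
    if not 0.0 < target_bvr <= 1.0:
        raise ValueError("target_bvr must lie in (0, 1]")
    if correlation_length < voxel_size:
        raise ValueError("correlation_length must be >= voxel_size")
    lo, hi = hu_bone
    if not lo < hi:
        raise ValueError("hu_bone must be an increasing interval")
    if hu_background >= lo:
        raise ValueError("hu_background must lie below the bone HU band")

    rng = np.random.default_rng(seed)
    fld = rng.standard_normal(shape)
    sigma_vox = correlation_length / voxel_size
    fld = ndimage.gaussian_filter(fld, sigma=sigma_vox, mode="wrap")

    threshold = np.quantile(fld, 1.0 - target_bvr)
    bone = fld >= threshold

    # denser strut cores: HU ramps with distance (in voxels) from marrow
    if bone.all():
        ramp = np.ones(shape)
    else:
        dist = ndimage.distance_transform_edt(bone)
        ramp = np.clip(dist / max(ramp_scale * sigma_vox, 1.0), 0.0, 1.0)
    hu = np.where(bone, lo + ramp * (hi - lo), hu_background)
    return HUImage(hu, voxel_size=voxel_size, hu_bone=hu_bone, hu_background=hu_background)


def _cylinder_masks(image: HUImage, defect: DefectSpec):
    """Boolean masks of the drill cylinder and anchor cylinder (voxel centers)."""
    ndim = image.ndim
    axis = defect.axis % ndim if ndim == 3 else None

    if ndim == 3:
        plane_axes = [a for a in range(3) if a != axis]
    else:
        plane_axes = [0, 1]
    if len(defect.center) != 2:
        raise ValueError("defect center must give the two in-plane coordinates")

    coords = [image.voxel_centers(a) for a in range(ndim)]
    grids = np.meshgrid(*coords, indexing="ij")
    dx = grids[plane_axes[0]] - defect.center[0]
    dy = grids[plane_axes[1]] - defect.center[1]
    r2 = dx * dx + dy * dy

    lo0, hi0 = image.origin[plane_axes[0]], image.origin[plane_axes[0]] + image.shape[plane_axes[0]] * image.voxel_size
    lo1, hi1 = image.origin[plane_axes[1]], image.origin[plane_axes[1]] + image.shape[plane_axes[1]] * image.voxel_size
    rad = defect.diameter / 2.0
    if (defect.center[0] - rad < lo0 or defect.center[0] + rad > hi0
            or defect.center[1] - rad < lo1 or defect.center[1] + rad > hi1):
        raise ValueError("defect cylinder extends outside the image in-plane")

    if ndim == 3:
        z = grids[axis]
        z_top = image.origin[axis] + image.shape[axis] * image.voxel_size
        extent = image.shape[axis] * image.voxel_size
        if defect.depth > extent:
            raise ValueError("defect depth exceeds the image extent along the drill axis")
        in_depth = z >= z_top - defect.depth
    else:
        in_depth = np.ones(image.shape, dtype=bool)

    hole = (r2 <= rad * rad) & in_depth
    anchor = (r2 <= (defect.anchor_diameter / 2.0) ** 2) & in_depth
    return hole, anchor


def drill_and_insert(image: HUImage, defect: DefectSpec):
    """Drill the defect and insert the anchor; return the modified image and labels.

    Voxels inside the drill cylinder are set to the background HU.  The label
    grid marks the anchor cylinder, the remaining void ring (empty when the
    anchor is press-fit), and classifies all other voxels as bone or marrow
    by the image's HU band.  The operation is idempotent on the labeled region.
    """
    hole, anchor = _cylinder_masks(image, defect)
    values = image.values.copy()
    values[hole] = image.hu_background

    out = HUImage(values, voxel_size=image.voxel_size, origin=image.origin,
                  hu_bone=image.hu_bone, hu_background=image.hu_background)
    labels = np.full(image.shape, REGION_MARROW, dtype=np.int8)
    labels[out.bone_mask()] = REGION_BONE
    labels[hole] = REGION_VOID
    labels[anchor] = REGION_ANCHOR
    return out, labels


def hu_histogram(image: HUImage, bins: int = 50) -> pd.DataFrame:
    """HU histogram as a DataFrame (bin edges and voxel counts)."""
    counts, edges = np.histogram(image.values, bins=bins)
    return pd.DataFrame({"hu_low": edges[:-1], "hu_high": edges[1:], "count": counts})


def write_hu_image(path, image: HUImage) -> None:
    """Write a multi-page TIFF stack plus a YAML sidecar with the metadata.

    3D images are stored with the last grid axis as the page axis; the sidecar
    (``<path>.yaml``) records voxel size, origin and the HU bands.
    """
    path = str(path)
    data = np.asarray(image.values, dtype=np.float32)
    if data.ndim == 3:
        data = np.moveaxis(data, 2, 0)  # pages along z
    tifffile.imwrite(path, data)
    meta = {
        "voxel_size_mm": float(image.voxel_size),
        "origin_mm": [float(c) for c in image.origin],
        "hu_bone": [float(image.hu_bone[0]), float(image.hu_bone[1])],
        "hu_background": float(image.hu_background),
        "ndim": int(image.ndim),
    }
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_hu_image(path) -> HUImage:
    """Read an image written by :func:`write_hu_image`."""
    path = str(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    with open(path + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta["ndim"] == 3:
        if data.ndim == 2:  # single-page stack
            data = data[None, ...]
        data = np.moveaxis(data, 0, 2)
    return HUImage(
        data,
        voxel_size=meta["voxel_size_mm"],
        origin=tuple(meta["origin_mm"]),
        hu_bone=tuple(meta["hu_bone"]),
        hu_background=meta["hu_background"],
    )
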