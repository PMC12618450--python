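"""Coulomb-friction push-out fixation estimate from interface pressure.

Swelling keeps the anchor-bone interface in compression; the axial force
needed to dislodge the anchor is estimated as the Coulomb friction integral
``F = mu * sum(max(p_i, 0) * A_i)`` over the lateral interface, with the
normal pressure extracted from the bone-side element stress at each
interface facet.  Comparing the estimate before and after remodeling
quantifies the fixation gained (or lost) through swelling-induced
densification.  Only the relative change is meaningful at this level of
idealization — there is no sliding-contact simulation here.

On the voxelized cylindrical interface the facets form a staircase of
axis-aligned faces; the contact normal is taken as the geometric (radial)
interface direction and each facet's area is projected onto it, so the
summed projected area approximates the true lateral surface and the force
is invariant to facet subdivision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem

__all__ = [
    "InterfaceFacet",
    "PushoutEstimate",
    "interface_facets",
    "interface_normal_pressure",
    "coulomb_pushout_force",
    "pushout_estimate",
    "compare_fixation",
]

_AXIS_NORMALS_2D = {0: (1.0, 0.0), 1: (0.0, 1.0)}


@dataclass(frozen=True)
class InterfaceFacet:
    """One element face between an anchor element and a bone element."""

    bone_element: int
    anchor_element: int
    centroid: np.ndarray  # mm
    normal: np.ndarray  # axis-aligned, pointing from anchor into bone
    area: float  # mm^2 (2D edges carry 1 mm thickness)


def interface_facets(mesh: fem.VoxelMesh) -> list:
    """All element faces separating the anchor region from bone."""
    region = np.full(mesh.grid_shape, -1, dtype=np.int8)
    region[tuple(mesh.grid_index.T)] = mesh.region
    elem_id = np.full(mesh.grid_shape, -1, dtype=np.int64)
    elem_id[tuple(mesh.grid_index.T)] = np.arange(mesh.n_elements)

    h = mesh.voxel_size
    dim = mesh.grid_index.shape[1]
    area = h ** (dim - 1)
    facets = []
    anchor_cells = mesh.grid_index[mesh.region == fem.REGION_ANCHOR]
    for cell in anchor_cells:
        center = np.asarray(mesh.origin) + (cell + 0.5) * h
        for axis in range(dim):
            for sign in (-1, 1):
                nb = cell.copy()
                nb[axis] += sign
                if np.any(nb < 0) or np.any(nb >= np.asarray(mesh.grid_shape)):
                    continue
                if region[tuple(nb)] != fem.REGION_BONE:
                    continue
                normal = np.zeros(dim)
                normal[axis] = float(sign)
                centroid = center.copy()
                centroid[axis] += sign * h / 2.0
                facets.append(InterfaceFacet(
                    bone_element=int(elem_id[tuple(nb)]),
                    anchor_element=int(elem_id[tuple(cell)]),
                    centroid=centroid, normal=normal, area=area,
                ))
    return facets


def _contact_normals(facets, mesh: fem.VoxelMesh, axis_point=None, axis: int = -1):
    """Geometric (radial) contact normal at each facet of a cylindrical interface."""
    dim = mesh.dim
    if axis_point is None:
        anchor_centers = mesh.centers[mesh.region == fem.REGION_ANCHOR]
        axis_point = anchor_centers.mean(axis=0)
    axis_point = np.asarray(axis_point, dtype=float)
    ax = axis % dim if dim == 3 else None
    normals = np.empty((len(facets), dim))
    for i, f in enumerate(facets):
        v = f.centroid - axis_point
        if ax is not None:
            v[ax] = 0.0
        norm = np.linalg.norm(v)
        normals[i] = v / norm if norm > 0 else f.normal
    return normals


def _normal_stress(voigt, n, dim):
    s = voigt
    if dim == 2:
        sig = np.array([[s[0], s[2]], [s[2], s[1]]])
    else:
        sig = np.array([
            [s[0], s[3], s[5]],
            [s[3], s[1], s[4]],
            [s[5], s[4], s[2]],
        ])
    return float(n @ sig @ n)


def interface_normal_pressure(state: fem.FieldState, mesh: fem.VoxelMesh,
                              facets=None, axis_point=None, axis: int = -1,
                              side: str = "both"):
    """Contact pressure p = -n . sigma . n (MPa) per interface facet.

    The contact normal is the radial interface direction; positive values are
    compression.  Traction is continuous across the interface but one-sided
    element-stress recovery on the voxel staircase is biased (the bone side
    under-reads and the anchor side over-reads by a comparable margin), so
    the default averages the two sides; ``side='bone'`` or ``'anchor'``
    selects a one-sided estimate.  Returns ``(pressures, projected_areas,
    facets)`` where the projected area is the facet area resolved onto the
    contact normal (the staircase-corrected lateral surface share).
    """
    if facets is None:
        facets = interface_facets(mesh)
    if not facets:
        raise ValueError("no anchor-bone interface facets on this mesh")
    if side not in ("both", "bone", "anchor"):
        raise ValueError("side must be 'both', 'bone' or 'anchor'")
    normals = _contact_normals(facets, mesh, axis_point, axis)
    dim = mesh.dim
    pressures = np.empty(len(facets))
    projected = np.empty(len(facets))
    for i, f in enumerate(facets):
        n = normals[i]
        vals = []
        if side in ("both", "bone"):
            vals.append(-_normal_stress(state.stress[f.bone_element], n, dim))
        if side in ("both", "anchor"):
            vals.append(-_normal_stress(state.stress[f.anchor_element], n, dim))
        pressures[i] = np.mean(vals)
        projected[i] = f.area * abs(float(n @ f.normal))
    return pressures, projected, facets


def coulomb_pushout_force(pressures, areas, mu: float = 0.4) -> float:
    """F = mu * sum(max(p, 0) * A) in N; tension facets carry no friction."""
    if mu < 0:
        raise ValueError("friction coefficient must be non-negative")
    p = np.asarray(pressures, dtype=float)
    a = np.asarray(areas, dtype=float)
    if p.shape != a.shape:
        raise ValueError("pressures and areas must have equal length")
    return float(mu * np.sum(np.maximum(p, 0.0) * a))


@dataclass(frozen=True)
class PushoutEstimate:
    mu: float
    pressures: np.ndarray  # MPa, per facet (signed; tension negative)
    areas: np.ndarray  # mm^2, projected onto the contact normal
    force: float  # N

    def __post_init__(self):
        if self.force < 0:
            raise ValueError("push-out force must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pressure_MPa": self.pressures,
                             "projected_area_mm2": self.areas})


def pushout_estimate(state: fem.FieldState, mesh: fem.VoxelMesh, mu: float = 0.4,
                     facets=None, axis_point=None, axis: int = -1) -> PushoutEstimate:
    """Full Coulomb push-out estimate for one solved field state."""
    pressures, areas, _ = interface_normal_pressure(state, mesh, facets, axis_point, axis)
    return PushoutEstimate(mu=mu, pressures=pressures, areas=areas,
                           force=coulomb_pushout_force(pressures, areas, mu))


def compare_fixation(pre: PushoutEstimate, post: PushoutEstimate) -> float:
    """Relative fixation change (F_post - F_pre) / F_pre."""
    if pre.force == 0:
        raise ValueError("pre-remodeling force is zero; relative change undefined")
    return (post.force - pre.force) / pre.force
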