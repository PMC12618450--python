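"""End-to-end orchestration: generate -> map -> swell/solve -> remodel -> analyze.

A single structured run configuration drives every stage; all defaults echo
the constants the method is built on (remodeling constants, calibration,
HU band, defect geometry), every output directory carries a full parameter
echo plus a config hash, and reruns with the same configuration are
bit-identical.

The packaged 2D demo models a transverse section through the implanted
vertebral ROI: a 16 x 16 mm heterogeneous trabecular continuum (plane
strain) with a press-fit 8 mm anchor at its center and the lateral boundary
held fixed, at roughly 4k voxel elements — small enough to iterate on a
laptop while preserving the compositional contrast between the three
swelling ratios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import bvr as bvr_mod
from . import fem, microct, pushout, remodeling, swelling, vtkio
from .materials import CalibrationConstants, MaterialState

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "demo_config",
    "run_pipeline",
    "run_free_swelling",
]

logger = logging.getLogger("swellanchor")


def _build(cls, data: dict, label: str):
    """Construct a config dataclass, rejecting unknown keys."""
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {label} config: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class ImageConfig:
    shape: tuple = (64, 64)
    voxel_size: float = 0.25
    target_bvr: float = 0.47
    correlation_length: float = 0.6
    hu_bone: tuple = (200.0, 1000.0)
    hu_background: float = 0.0
    seed: int = 7


@dataclass(frozen=True)
class DefectConfig:
    diameter: float = 8.0
    depth: float = 10.0
    anchor_diameter: float = 8.0  # press-fit


@dataclass(frozen=True)
class MaterialsConfig:
    poisson: float = 0.3
    anchor_modulus: float = 2500.0  # MPa; demo uses the swollen-state value


@dataclass(frozen=True)
class ROIConfig:
    inner_radius: float = 4.0
    thickness: float = 2.0
    height: float = 10.0
    # far-field ROI: deterministic in-plane offsets (mm) of sphere centers (3D),
    # or an annulus [inner_radius, inner_radius + thickness] in 2D
    far_offsets: tuple = ((5.5, 0.0), (-5.5, 0.0))
    far_inner_radius: float = 6.5
    far_thickness: float = 1.0


@dataclass(frozen=True)
class PushoutConfig:
    mu: float = 0.4


@dataclass(frozen=True)
class PipelineConfig:
    composition: str = "85/15"
    saturation: float = 1.0
    overload: bool = True  # quadratic overload branch (D > 0) vs linear law
    # when set, the modeled region is a disc (2D) / cylinder (3D) of this
    # radius around the defect axis — the ROI shell the method analyzes;
    # voxels outside it are excluded from the mesh
    domain_radius: float = None
    image: ImageConfig = field(default_factory=ImageConfig)
    defect: DefectConfig = field(default_factory=DefectConfig)
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    materials: MaterialsConfig = field(default_factory=MaterialsConfig)
    remodeling: remodeling.RemodelingParams = field(default_factory=remodeling.RemodelingParams)
    roi: ROIConfig = field(default_factory=ROIConfig)
    pushout: PushoutConfig = field(default_factory=PushoutConfig)
    output: str = "runs/swellanchor"

    def __post_init__(self):
        swelling.get_composition(self.composition)  # raises with valid labels

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        nested = {
            "image": ImageConfig, "defect": DefectConfig,
            "calibration": CalibrationConstants, "materials": MaterialsConfig,
            "remodeling": remodeling.RemodelingParams, "roi": ROIConfig,
            "pushout": PushoutConfig,
        }
        kwargs = {}
        for key, sub in nested.items():
            if key in data:
                block = data.pop(key)
                kwargs[key] = block if isinstance(block, sub) else _build(sub, block, key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown keys in pipeline config: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for stable serialization
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def demo_config(composition: str = "85/15", output: str = "runs/demo", **overrides) -> PipelineConfig:
    """The packaged 2D demo configuration (fixed seed, ~5k elements).

    A plane-strain transverse section through the implanted ROI: a 6 mm
    radius continuum disc of heterogeneous HU-mapped bone with the press-fit
    8 mm anchor at its center and the outer boundary held fixed — the
    desk-scale analogue of the thin ROI shell the method meshes around the
    drill hole.  The anchor modulus is the swollen-state value (100 MPa):
    once saturated, the hydrated co-polymer is orders of magnitude softer
    than its dry glassy state, and the interface pressure — hence the
    remodeling regime each composition lands in — scales with it.
    """
    base = {
        "composition": composition,
        "domain_radius": 6.0,
        "image": ImageConfig(shape=(84, 84), voxel_size=0.15),
        "materials": MaterialsConfig(anchor_modulus=100.0),
        "remodeling": remodeling.RemodelingParams(resolve_every=1000, max_steps=120_000),
        "roi": ROIConfig(inner_radius=4.0, thickness=1.0,
                         far_inner_radius=5.0, far_thickness=1.0),
        "output": output,
    }
    base.update(overrides)
    return PipelineConfig(**base)


@dataclass
class PipelineResult:
    config: PipelineConfig
    mesh: fem.VoxelMesh
    material_initial: MaterialState
    material_final: MaterialState
    history: remodeling.RemodelingHistory
    state_initial: fem.FieldState
    state_final: fem.FieldState
    pushout_pre: pushout.PushoutEstimate
    pushout_post: pushout.PushoutEstimate
    fixation_change: float
    interface_mask: np.ndarray
    regime_table: pd.DataFrame
    bvr_interface: float
    bvr_far: float
    outdir: str = None

    @property
    def mean_interface_density_initial(self) -> float:
        bone = self.mesh.region == fem.REGION_BONE
        sel = bone & self.interface_mask
        return float(self.material_initial.density[sel].mean())

    @property
    def mean_interface_density_final(self) -> float:
        bone = self.mesh.region == fem.REGION_BONE
        sel = bone & self.interface_mask
        return float(self.material_final.density[sel].mean())

    @property
    def n_floored_interface(self) -> int:
        bone = self.mesh.region == fem.REGION_BONE
        sel = bone & self.interface_mask
        p = self.config.remodeling
        return int(np.sum(self.material_final.density[sel] <= p.rho_min * (1 + 1e-9)))


def _generate_stage(cfg: PipelineConfig):
    img = microct.generate_trabecular_image(
        shape=tuple(cfg.image.shape), voxel_size=cfg.image.voxel_size,
        target_bvr=cfg.image.target_bvr,
        correlation_length=cfg.image.correlation_length,
        hu_bone=tuple(cfg.image.hu_bone), hu_background=cfg.image.hu_background,
        seed=cfg.image.seed)
    ndim = img.ndim
    extent = [img.shape[a] * img.voxel_size for a in range(ndim)]
    if ndim == 3:
        center = (extent[0] / 2.0, extent[1] / 2.0)
    else:
        center = (extent[0] / 2.0, extent[1] / 2.0)
    defect = microct.DefectSpec(center=center, diameter=cfg.defect.diameter,
                                depth=cfg.defect.depth,
                                anchor_diameter=cfg.defect.anchor_diameter)
    drilled, labels = microct.drill_and_insert(img, defect)
    if cfg.domain_radius is not None:
        plane = [0, 1] if ndim == 2 else [0, 1]
        grids = np.meshgrid(*[drilled.voxel_centers(a) for a in range(ndim)],
                            indexing="ij")
        rr = np.hypot(grids[plane[0]] - center[0], grids[plane[1]] - center[1])
        labels = labels.copy()
        labels[rr > cfg.domain_radius] = microct.REGION_VOID
    return drilled, labels, center


def _interface_mask_for(mesh: fem.VoxelMesh, center, cfg: PipelineConfig) -> np.ndarray:
    centers = mesh.centers
    if mesh.dim == 3:
        d2 = (centers[:, 0] - center[0]) ** 2 + (centers[:, 1] - center[1]) ** 2
    else:
        d2 = (centers[:, 0] - center[0]) ** 2 + (centers[:, 1] - center[1]) ** 2
    r = np.sqrt(d2)
    return (r >= cfg.roi.inner_radius) & (r < cfg.roi.inner_radius + cfg.roi.thickness)


def _bvr_stage(result_mat, mesh, center, cfg: PipelineConfig):
    """BVR of the projected post-remodeling HU image: interface vs far field."""
    img = bvr_mod.density_to_hu_projection(result_mat, mesh, cfg.calibration,
                                           hu_bone=tuple(cfg.image.hu_bone),
                                           hu_background=cfg.image.hu_background)
    interface_roi = bvr_mod.hollow_cylinder_mask(
        img, center, inner_radius=cfg.roi.inner_radius,
        thickness=cfg.roi.thickness, height=cfg.roi.height)
    ratio_if = bvr_mod.bone_volume_ratio(img, interface_roi, label="V1/V0").ratio
    if img.ndim == 3:
        v0 = interface_roi.volume
        far = []
        for off in cfg.roi.far_offsets:
            c = (center[0] + off[0], center[1] + off[1],
                 img.origin[2] + img.shape[2] * img.voxel_size / 2.0)
            roi = bvr_mod.equal_volume_sphere_mask(img, c, v0)
            far.append(bvr_mod.bone_volume_ratio(img, roi, label="V2/V0").ratio)
        ratio_far = float(np.mean(far))
    else:
        far_roi = bvr_mod.hollow_cylinder_mask(
            img, center, inner_radius=cfg.roi.far_inner_radius,
            thickness=cfg.roi.far_thickness)
        ratio_far = bvr_mod.bone_volume_ratio(img, far_roi, label="V2/V0").ratio
    return img, ratio_if, ratio_far


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute every stage of the swelling-remodeling study for one config."""
    logger.info("stage: generate (seed=%d)", cfg.image.seed)
    drilled, labels, center = _generate_stage(cfg)

    logger.info("stage: mesh + material mapping")
    mode = "3d" if drilled.ndim == 3 else "plane_strain"
    mesh = fem.VoxelMesh.from_labels(labels, drilled.voxel_size,
                                     origin=drilled.origin, mode=mode)
    hu_elements = drilled.values[tuple(mesh.grid_index.T)]
    p = cfg.remodeling
    if not cfg.overload:
        p = dataclasses.replace(p, D=0.0)
    mat0 = MaterialState.from_hu(hu_elements,
                                 anchor_mask=mesh.region == fem.REGION_ANCHOR,
                                 anchor_modulus=cfg.materials.anchor_modulus,
                                 poisson=cfg.materials.poisson,
                                 cal=cfg.calibration,
                                 rho_min=p.rho_min, rho_max=p.rho_max)

    comp = swelling.get_composition(cfg.composition)
    eig = swelling.linear_swelling_strain(comp, cfg.saturation)
    bc = fem.BoundaryConditions.constrained_lateral(mesh)

    logger.info("stage: pre-remodeling swelling solve (eigenstrain=%.6f)", eig)
    state0 = fem.solve_hygroelastic(mesh, mat0, eig, bc)
    est_pre = pushout.pushout_estimate(state0, mesh, mu=cfg.pushout.mu)

    logger.info("stage: remodeling (W=%d, dt=%g)", p.resolve_every, p.dt)
    history, mat_final, state_final = remodeling.run_remodeling(
        mesh, mat0, eig, bc, p, cal=cfg.calibration, keep_snapshots=False)

    logger.info("stage: post-remodeling analysis")
    est_post = pushout.pushout_estimate(state_final, mesh, mu=cfg.pushout.mu)
    change = pushout.compare_fixation(est_pre, est_post)

    interface_mask = _interface_mask_for(mesh, center, cfg)
    S_final = fem.stimulus_field(state_final, mat_final, mesh)
    _, regime_table = remodeling.classify_elements(mat_final, S_final, mesh, p,
                                                   interface_mask=interface_mask)
    projected, ratio_if, ratio_far = _bvr_stage(mat_final, mesh, center, cfg)

    result = PipelineResult(
        config=cfg, mesh=mesh, material_initial=mat0, material_final=mat_final,
        history=history, state_initial=state0, state_final=state_final,
        pushout_pre=est_pre, pushout_post=est_post, fixation_change=change,
        interface_mask=interface_mask, regime_table=regime_table,
        bvr_interface=ratio_if, bvr_far=ratio_far,
    )
    if write_outputs:
        result.outdir = _write_outputs(result, drilled, projected)
    return result


def _report_text(result: PipelineResult) -> str:
    cfg = result.config
    lines = [
        "swellanchor run report",
        f"config_hash: {cfg.config_hash()}",
        f"composition: {cfg.composition} (saturation {cfg.saturation})",
        f"elements: {result.mesh.n_elements} "
        f"(bone {int(np.sum(result.mesh.region == fem.REGION_BONE))}, "
        f"anchor {int(np.sum(result.mesh.region == fem.REGION_ANCHOR))})",
        f"remodeling checkpoints: {result.history.n_checkpoints} "
        f"(converged: {result.history.converged}, euler steps: {result.history.steps})",
        f"mean interface density: {result.mean_interface_density_initial:.4f} -> "
        f"{result.mean_interface_density_final:.4f} g/cm3",
        f"floored interface elements: {result.n_floored_interface}",
        f"push-out force: pre {result.pushout_pre.force:.3f} N, "
        f"post {result.pushout_post.force:.3f} N "
        f"({100 * result.fixation_change:+.2f}%)",
        f"bone volume ratio: interface {result.bvr_interface:.4f}, "
        f"far {result.bvr_far:.4f}",
        "",
        "regime counts by region:",
        result.regime_table.to_string(index=False),
        "",
    ]
    return "\n".join(lines)


def _write_outputs(result: PipelineResult, drilled_image, projected_image) -> str:
    cfg = result.config
    outdir = cfg.output
    os.makedirs(outdir, exist_ok=True)
    meta = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
            "converged": bool(result.history.converged),
            "euler_steps": int(result.history.steps)}
    with open(os.path.join(outdir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(_report_text(result))
    result.history.summary.to_csv(os.path.join(outdir, "history.csv"), index=False)
    result.regime_table.to_csv(os.path.join(outdir, "regimes.csv"), index=False)
    result.pushout_pre.to_frame().to_csv(os.path.join(outdir, "pushout_pre.csv"), index=False)
    result.pushout_post.to_frame().to_csv(os.path.join(outdir, "pushout_post.csv"), index=False)
    microct.write_hu_image(os.path.join(outdir, "input_hu.tif"), drilled_image)
    microct.write_hu_image(os.path.join(outdir, "projected_hu.tif"), projected_image)
    vtkio.write_field_state(
        os.path.join(outdir, "fields_final.vtk"), result.mesh, result.state_final,
        extra_cell_data={"density_g_cm3": result.material_final.density,
                         "density_initial": result.material_initial.density})
    logger.info("outputs written to %s", outdir)
    return outdir


def run_free_swelling(compositions=None, diameter0: float = 8.0, length0: float = 8.0,
                      voxel_size: float = 0.5, saturation: float = 1.0,
                      anchor_modulus: float = 2500.0, poisson: float = 0.3) -> pd.DataFrame:
    """Free-swelling FE vs closed form for each composition (patch test).

    Meshes the anchor's axial section (diameter x length rectangle, plane
    stress), applies the composition eigenstrain to the whole body under
    minimal rigid-body constraints, and measures the diameter and length
    change from the boundary node displacements.  The relative FE error
    against ``d0 * beta_h * delta_alpha`` must sit at machine precision.
    """
    if compositions is None:
        compositions = list(swelling.COMPOSITIONS)
    nx = max(2, int(round(diameter0 / voxel_size)))
    ny = max(2, int(round(length0 / voxel_size)))
    labels = fem.make_block_labels((nx, ny), region=microct.REGION_ANCHOR)
    mesh = fem.VoxelMesh.from_labels(labels, voxel_size, mode="plane_stress")
    d_actual = nx * voxel_size
    l_actual = ny * voxel_size
    mat = MaterialState(np.ones(mesh.n_elements),
                        np.full(mesh.n_elements, anchor_modulus), poisson)
    bc = fem.BoundaryConditions.free_swelling(mesh)
    rows = []
    for label in compositions:
        comp = (label if isinstance(label, swelling.SwellingComposition)
                else swelling.get_composition(label))
        label = comp.label
        e = swelling.linear_swelling_strain(comp, saturation)
        state = fem.solve_hygroelastic(mesh, mat, {"all": e}, bc)
        x = mesh.nodes[:, 0] + state.displacement[:, 0]
        y = mesh.nodes[:, 1] + state.displacement[:, 1]
        dd_fe = (x.max() - x.min()) - d_actual
        dl_fe = (y.max() - y.min()) - l_actual
        dd_ref, dl_ref = swelling.free_swelling_prediction(d_actual, l_actual, comp, saturation)
        denom = max(abs(dd_ref), 1e-30)
        rows.append({
            "composition": label, "eigenstrain": e,
            "dd_fe_mm": dd_fe, "dd_closed_form_mm": dd_ref,
            "dl_fe_mm": dl_fe, "dl_closed_form_mm": dl_ref,
            "rel_error": abs(dd_fe - dd_ref) / denom,
            "max_abs_stress_MPa": float(np.abs(state.stress).max()),
        })
    return pd.DataFrame(rows)
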