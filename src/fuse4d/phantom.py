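"""Synthetic 4D multimodal phantom: a breathing spherical lesion imaged by
several sources, each on its own grid, mirroring a clinical multi-source
layout (full-body CT, 4D-CT, 4D-PET with 10 bins, planning CT, delineations,
dose volume) at desk scale.

The grids keep the clinical resolution ratios (PET voxels ~4x coarser than
the planning CT in-plane, coarse dose grid) while staying small enough that
a full pipeline run takes seconds.  Motion is a sinusoidal cranio-caudal
(z) displacement of the lesion; the internal target volume (ITV) is the
voxelwise union of the per-bin lesion masks on the planning grid.  A
ground-truth manifest records everything the generator knows, so recovery
tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .contours import PlanarContour, Structure, StructureSet
from .volume import BinaryVolume, DoseVolume, Grid3D, ScalarVolume

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "make_breathing_trajectory",
    "make_phantom",
    "make_dose",
]

LUNG_HU = -800.0
SOFT_TISSUE_HU = 40.0
AIRWAY_HU = -1000.0
MEDIASTINUM_HU = 30.0


@dataclass
class GridSpec:
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]

    def grid(self) -> Grid3D:
        return Grid3D(np.array(self.origin), np.array(self.spacing), self.dims)


def _centered(spacing, dims) -> GridSpec:
    spacing = np.asarray(spacing, float)
    dims = np.asarray(dims, int)
    origin = -(dims - 1) * spacing / 2.0
    return GridSpec(tuple(spacing), tuple(int(d) for d in dims), tuple(origin))


@dataclass
class PhantomSpec:
    """Parameters of the synthetic breathing phantom.

    Grid defaults preserve the clinical layout's resolution ratios at a
    scaled-down extent (~10 cm thorax section): 1x1x3 mm planning CT,
    1.2x1.2x2 mm 4D-CT, 4 mm isotropic 4D-PET with 10 bins, coarse
    full-body CT and 3 mm dose grid.
    """

    # grids: (spacing mm, dims)
    body_ct: GridSpec = field(default_factory=lambda: _centered((2.0, 2.0, 4.0), (64, 64, 60)))
    ct4d: GridSpec = field(default_factory=lambda: _centered((1.2, 1.2, 2.0), (80, 80, 50)))
    pet4d: GridSpec = field(default_factory=lambda: _centered((4.0, 4.0, 4.0), (24, 24, 24)))
    planning_ct: GridSpec = field(default_factory=lambda: _centered((1.0, 1.0, 3.0), (96, 96, 32)))
    dose_grid: GridSpec = field(default_factory=lambda: _centered((3.0, 3.0, 3.0), (32, 32, 32)))

    # lesion and motion
    lesion_center: tuple[float, float, float] = (8.0, 4.0, 0.0)
    lesion_radius_mm: float = 8.0
    amplitude_mm: float = 10.0
    bins: int = 10

    # imaging
    pet_contrast: float = 8.0  # uptake multiple of background
    pet_background: float = 1.0
    pet_blur_mm: float = 4.0
    ct_noise_hu: float = 20.0
    pet_noise_frac: float = 0.05

    # organs at risk: airway = tube along z, mediastinum = slab
    airway_center_xy: tuple[float, float] = (-28.0, 0.0)
    airway_radius_mm: float = 5.0
    mediastinum_x_range: tuple[float, float] = (-48.0, -36.0)

    # dose
    prescription_gy: float = 54.0
    falloff_mm: float = 4.0

    seed: int = 0

    def __post_init__(self):
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.bins < 1:
            raise ValueError("need at least one time bin")
        if self.amplitude_mm < 0:
            raise ValueError("breathing amplitude must be >= 0")


@dataclass
class PhantomBundle:
    body_ct: ScalarVolume
    ct4d: ScalarVolume
    pet4d: ScalarVolume
    planning_ct: ScalarVolume
    structures: StructureSet
    lesion_bins: list[BinaryVolume]  # per-bin lesion masks on the planning grid
    itv: BinaryVolume
    airway: BinaryVolume
    mediastinum: BinaryVolume
    dose: DoseVolume
    manifest: dict


def make_breathing_trajectory(amplitude_mm: float, bins: int) -> np.ndarray:
    """Per-bin lesion displacement vectors (mm): sinusoidal cranio-caudal
    motion, d_z(t) = A sin(2 pi t / B), t = 0..B-1."""
    if bins < 1:
        raise ValueError("need at least one time bin")
    t = np.arange(bins)
    d = np.zeros((bins, 3))
    d[:, 2] = amplitude_mm * np.sin(2.0 * np.pi * t / bins)
    return d


def _voxel_centers(grid: Grid3D) -> np.ndarray:
    idx = np.indices(grid.dims).reshape(3, -1).T.astype(float)
    return grid.voxel_to_world(idx)


def _sphere_mask(grid: Grid3D, center, radius) -> np.ndarray:
    pts = _voxel_centers(grid)
    inside = np.linalg.norm(pts - np.asarray(center), axis=1) <= radius
    return inside.reshape(grid.dims)


def make_dose(target: BinaryVolume, prescription_gy: float, falloff_mm: float,
              grid: Grid3D) -> DoseVolume:
    """Synthetic dose distribution: prescription-level plateau inside the
    target with a logistic falloff of characteristic length ``falloff_mm``
    around its surface, dose(p) = prescription * sigma(-s(p)/falloff) with
    s the signed distance to the target surface (negative inside)."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0 Gy")
    if falloff_mm <= 0:
        raise ValueError("falloff length must be > 0 mm")
    fg = target.frame(0).astype(bool)
    if not fg.any():
        raise ValueError("empty target")
    # target membership at dose-grid voxel centres
    if grid == target.grid:
        member = fg
    else:
        pts = _voxel_centers(grid)
        member = target.contains(pts).reshape(grid.dims)
    if member.any():
        d_out = distance_transform_edt(~member, sampling=grid.spacing)
        d_in = distance_transform_edt(member, sampling=grid.spacing)
        signed = np.where(member, -d_in, d_out)
    else:
        # target smaller than a dose voxel: fall back to distance from the
        # nearest target centre so the falloff is still anchored
        pts = _voxel_centers(grid)
        centers = target.grid.voxel_to_world(np.argwhere(fg).astype(float))
        from scipy.spatial import cKDTree

        signed, _ = cKDTree(centers).query(pts)
        signed = signed.reshape(grid.dims)
    dose = prescription_gy / (1.0 + np.exp(signed / falloff_mm))
    return DoseVolume(grid, np.clip(dose, 0.0, prescription_gy))


def _lesion_contours(grid: Grid3D, center, radius, n_vertices: int = 72):
    """Polygonal circle contours of a sphere on the grid's slice positions."""
    contours = []
    zs = grid.origin[2] + np.arange(grid.dims[2]) * grid.spacing[2]
    for z in zs:
        dz = z - center[2]
        if abs(dz) >= radius:
            continue
        r = float(np.sqrt(radius**2 - dz**2))
        ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        verts = np.column_stack(
            [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
        )
        contours.append(PlanarContour(float(z), verts))
    return contours


def make_phantom(spec: PhantomSpec = None) -> PhantomBundle:
    """Generate the full multi-source bundle from one seeded specification."""
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    traj = make_breathing_trajectory(spec.amplitude_mm, spec.bins)
    centers = np.asarray(spec.lesion_center) + traj

    ct4d_grid = spec.ct4d.grid()
    lo, hi = ct4d_grid.local_bounds()
    for c in centers:
        local = c - ct4d_grid.origin
        if np.any(local - spec.lesion_radius_mm < lo) or np.any(
            local + spec.lesion_radius_mm > hi
        ):
            raise ValueError(
                f"lesion at {c} (r={spec.lesion_radius_mm} mm) leaves the 4D-CT grid"
            )

    # ---- anatomy helpers -------------------------------------------------
    def anatomy_hu(grid: Grid3D, lesion_center=None) -> np.ndarray:
        pts = _voxel_centers(grid)
        hu = np.full(len(pts), LUNG_HU)
        med = (pts[:, 0] >= spec.mediastinum_x_range[0]) & (
            pts[:, 0] <= spec.mediastinum_x_range[1]
        )
        hu[med] = MEDIASTINUM_HU
        r_xy = np.hypot(
            pts[:, 0] - spec.airway_center_xy[0], pts[:, 1] - spec.airway_center_xy[1]
        )
        hu[r_xy <= spec.airway_radius_mm] = AIRWAY_HU
        if lesion_center is not None:
            lesion = (
                np.linalg.norm(pts - np.asarray(lesion_center), axis=1)
                <= spec.lesion_radius_mm
            )
            hu[lesion] = SOFT_TISSUE_HU
        return hu.reshape(grid.dims)

    # ---- image sources ---------------------------------------------------
    body_grid = spec.body_ct.grid()
    body = anatomy_hu(body_grid, centers[0])
    body = body + rng.normal(0.0, spec.ct_noise_hu, body.shape)
    body_ct = ScalarVolume(body_grid, [body], modality="CT", units="HU", name="body_ct")

    ct_frames = []
    for c in centers:
        f = anatomy_hu(ct4d_grid, c)
        ct_frames.append(f + rng.normal(0.0, spec.ct_noise_hu, f.shape))
    ct4d = ScalarVolume(ct4d_grid, ct_frames, modality="CT", units="HU", name="4d_ct")

    pet_grid = spec.pet4d.grid()
    pet_frames = []
    sigma_vox = spec.pet_blur_mm / np.asarray(pet_grid.spacing)
    for c in centers:
        uptake = _sphere_mask(pet_grid, c, spec.lesion_radius_mm).astype(float)
        blob = gaussian_filter(uptake, sigma_vox)
        f = spec.pet_background * (1.0 + (spec.pet_contrast - 1.0) * blob)
        noise = rng.normal(0.0, spec.pet_noise_frac, f.shape) * np.sqrt(
            np.maximum(f, 0.0)
        )
        pet_frames.append(np.maximum(f + noise, 0.0))
    pet4d = ScalarVolume(
        pet_grid, pet_frames, modality="PET", units="activity", name="4d_pet"
    )

    plan_grid = spec.planning_ct.grid()
    plan = anatomy_hu(plan_grid, centers[0])
    plan = plan + rng.normal(0.0, spec.ct_noise_hu, plan.shape)
    planning_ct = ScalarVolume(
        plan_grid, [plan], modality="CT", units="HU", name="planning_ct"
    )

    # ---- delineations on the planning grid --------------------------------
    lesion_bins = []
    for t, c in enumerate(centers):
        m = _sphere_mask(plan_grid, c, spec.lesion_radius_mm).astype(np.uint8)
        lesion_bins.append(
            BinaryVolume(plan_grid, [m], name=f"lesion_bin{t}", color=(1, 0.5, 0, 1))
        )
    itv_mask = np.zeros(plan_grid.dims, dtype=np.uint8)
    for b in lesion_bins:
        itv_mask |= b.frames[0]
    itv = BinaryVolume(plan_grid, [itv_mask], name="itv", color=(1, 1, 0, 1))

    airway_mask = np.zeros(plan_grid.dims, dtype=bool)
    pts = _voxel_centers(plan_grid)
    r_xy = np.hypot(
        pts[:, 0] - spec.airway_center_xy[0], pts[:, 1] - spec.airway_center_xy[1]
    )
    airway_mask = (r_xy <= spec.airway_radius_mm).reshape(plan_grid.dims)
    airway = BinaryVolume(
        plan_grid, [airway_mask.astype(np.uint8)], name="bronchial_tree",
        color=(0, 1, 1, 1),
    )
    med_mask = (
        (pts[:, 0] >= spec.mediastinum_x_range[0])
        & (pts[:, 0] <= spec.mediastinum_x_range[1])
    ).reshape(plan_grid.dims)
    mediastinum = BinaryVolume(
        plan_grid, [med_mask.astype(np.uint8)], name="mediastinum", color=(0, 0.4, 1, 1)
    )

    # structure set: per-bin lesion contours + static ITV/OAR entries
    structures = {
        "lesion": Structure(
            "lesion",
            [_lesion_contours(plan_grid, c, spec.lesion_radius_mm) for c in centers],
            color=(1, 0.5, 0, 1),
            role="target",
        ),
    }
    # frame-of-reference string kept UID-shaped so DICOM-RTSS export is valid
    ss = StructureSet(structures, frame_of_reference="1.2.826.0.1.3680043.10.424.1")

    # ---- dose -------------------------------------------------------------
    dose = make_dose(itv, spec.prescription_gy, spec.falloff_mm, spec.dose_grid.grid())

    # ---- ground-truth manifest --------------------------------------------
    from .dvh import in_mask_doses

    itv_doses = in_mask_doses(dose, itv)
    coverage_half_rx = float(np.mean(itv_doses >= spec.prescription_gy / 2.0))
    manifest = {
        "seed": spec.seed,
        "bins": spec.bins,
        "amplitude_mm": spec.amplitude_mm,
        "lesion_radius_mm": spec.lesion_radius_mm,
        "lesion_center_mm": list(spec.lesion_center),
        "true_centers_mm": centers.tolist(),
        "true_lesion_volume_mm3": 4.0 / 3.0 * np.pi * spec.lesion_radius_mm**3,
        "itv_voxel_volume_mm3": float(itv_mask.sum()) * plan_grid.voxel_volume(),
        "prescription_gy": spec.prescription_gy,
        "falloff_mm": spec.falloff_mm,
        "dose_coverage_half_rx": coverage_half_rx,
        "pet_contrast": spec.pet_contrast,
    }

    return PhantomBundle(
        body_ct=body_ct,
        ct4d=ct4d,
        pet4d=pet4d,
        planning_ct=planning_ct,
        structures=ss,
        lesion_bins=lesion_bins,
        itv=itv,
        airway=airway,
        mediastinum=mediastinum,
        dose=dose,
        manifest=manifest,
    )
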