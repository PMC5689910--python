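"""Interaction layer: surface point picking for 3D-to-2D slice navigation,
Euclidean margin expansion, and central/peripheral tumour-location
classification via margin-volume intersection.

A lesion is "central" when its internal target volume overlaps a margin
volume around a proximal structure (bronchial tree, mediastinum); otherwise
it is "peripheral".  Margins default to 20 mm around the bronchial tree and
5 mm around the mediastinum and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .render import Camera, Scene, render
from .volume import BinaryVolume

__all__ = [
    "PickResult",
    "MarginVolume",
    "pick_surface_point",
    "dilate",
    "intersection_volume",
    "classify_location",
    "DEFAULT_MARGINS_MM",
]

DEFAULT_MARGINS_MM = {"bronchial_tree": 20.0, "mediastinum": 5.0}


@dataclass
class PickResult:
    """Picked surface point: the structure it belongs to, its world position,
    the reference-volume voxel index for slice navigation, and the ray depth."""

    structure: str
    point_mm: np.ndarray
    voxel_index: tuple[int, int, int]
    depth_mm: float


@dataclass
class MarginVolume:
    """A base structure expanded by an isotropic Euclidean margin."""

    base_name: str
    margin_mm: float
    mask: BinaryVolume


def pick_surface_point(scene: Scene, camera: Camera, pixel) -> PickResult | None:
    """Pick the closest delineation surface point along the pixel's viewing
    ray (inside the clip ROI); ``None`` over background.

    ``pixel`` is (row, col) in image coordinates.  The returned voxel index
    is in the scene's reference grid, ready for re-centring 2D slice views.
    """
    row, col = int(pixel[0]), int(pixel[1])
    if not (0 <= row < camera.height and 0 <= col < camera.width):
        raise ValueError(f"pixel {pixel} outside a {camera.height}x{camera.width} image")
    # render a 1-pixel camera along the same ray: cheap and reuses the exact
    # marching/crossing machinery, so pick and depth buffer agree by design
    origins, dirs = camera.rays()
    ray_o = origins[row * camera.width + col]
    ray_d = dirs[row * camera.width + col]
    sub = Camera(
        eye=ray_o,
        look_at=ray_o + ray_d,
        up=camera.up,
        fov_deg=1e-3 if not camera.orthographic else camera.fov_deg,
        width=1,
        height=1,
        orthographic=camera.orthographic,
        ortho_height=1e-6 if camera.orthographic else camera.ortho_height,
    )
    # only binary (delineation) surfaces are pickable
    pick_scene = Scene(
        reference=scene.reference,
        image_layers=[],
        surface_layers=[s for s in scene.surface_layers if s.enabled and _is_binary(s)],
        masks=scene.masks,
        roi=scene.roi,
        time_bin=scene.time_bin,
        step_mm=scene.step_size(),
        early_termination=False,
    )
    res = render(pick_scene, sub)
    depth = float(res.depth[0, 0])
    if not np.isfinite(depth):
        return None
    si = int(res.hit_structure[0, 0])
    point = res.hit_point[0, 0]
    idx = np.rint(scene.reference.world_to_voxel(point)).astype(int)
    idx = np.clip(idx, 0, np.array(scene.reference.dims) - 1)
    return PickResult(
        structure=pick_scene.surface_layers[si].name,
        point_mm=point,
        voxel_index=tuple(int(i) for i in idx),
        depth_mm=depth,
    )


def _is_binary(surface) -> bool:
    return isinstance(surface.source, BinaryVolume)


def dilate(b: BinaryVolume, margin_mm: float) -> BinaryVolume:
    """Euclidean dilation: foreground becomes every voxel whose centre is
    within ``margin_mm`` of any input foreground voxel centre, respecting
    anisotropic spacing.  A zero margin is the identity."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0 mm")
    frames = []
    for f in b.frames:
        if margin_mm == 0 or not f.any():
            frames.append(f.copy())
            continue
        dist = distance_transform_edt(~f.astype(bool), sampling=b.grid.spacing)
        frames.append((dist <= margin_mm + 1e-9).astype(np.uint8))
    return BinaryVolume(b.grid, frames, name=f"{b.name}+{margin_mm:g}mm", color=b.color)


def intersection_volume(a: BinaryVolume, b: BinaryVolume, t: int = 0):
    """Overlap of two masks, reported on ``a``'s grid: ``b`` is
    membership-tested at ``a``'s foreground voxel centres (grids may differ).

    Returns ``(volume_mm3, mask)`` where the mask marks the overlap on
    ``a``'s grid — the region a highlight render mode would tint.
    """
    fa = a.frame(t).astype(bool)
    if a.grid == b.grid:
        inter = fa & b.frame(t).astype(bool)
    else:
        inter = np.zeros(a.grid.dims, dtype=bool)
        idx = np.argwhere(fa)
        if len(idx):
            pts = a.grid.voxel_to_world(idx.astype(float))
            member = b.contains(pts, t)
            inter[tuple(idx[member].T)] = True
    volume = float(inter.sum()) * a.grid.voxel_volume()
    return volume, BinaryVolume(
        a.grid, [inter.astype(np.uint8)], name=f"{a.name}&{b.name}"
    )


def classify_location(itv: BinaryVolume, margins: list[MarginVolume], t: int = 0):
    """Classify a lesion as central or peripheral.

    Central iff the ITV overlaps (any positive volume) at least one margin
    volume; the report lists the overlap with each margin in mm^3.
    """
    if not margins:
        raise ValueError("need at least one margin volume")
    if not itv.frame(t).any():
        raise ValueError("empty ITV")
    report = {}
    central = False
    for m in margins:
        vol, _ = intersection_volume(itv, m.mask, t)
        report[m.base_name] = {"margin_mm": m.margin_mm, "overlap_mm3": vol}
        central = central or vol > 0
    return ("central" if central else "peripheral"), report
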