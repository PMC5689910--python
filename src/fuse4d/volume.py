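"""Unified world-coordinate data model for mixed-resolution 3D/4D volumes.

Every image source (full-body CT, 4D-CT, 4D-PET, planning CT, delineations,
dose) lives on its *own* grid; nothing is ever resampled onto another grid.
Fusion happens by sampling each source in world coordinates (mm) at render
time, which is what allows a 4-mm PET and a 1-mm CT to be combined without
preprocessing.

Conventions
-----------
* All world units are millimetres.
* Voxel indexing is 0-based with the voxel-centre convention: voxel ``i``
  covers the half-open world slab
  ``[origin + i*spacing - spacing/2, origin + i*spacing + spacing/2)``
  along each axis (in the grid's local frame).
* Direction matrices are orthonormal (DICOM patient orientations are);
  sheared grids are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid3D",
    "ScalarVolume",
    "BinaryVolume",
    "DoseVolume",
    "WindowLevel",
    "TransferFunction",
    "tf_from_window",
    "crop_to_content",
]


@dataclass(frozen=True)
class Grid3D:
    """Geometry of one volume: origin (mm), per-axis spacing (mm), voxel
    counts and an orthonormal 3x3 direction matrix whose columns are the
    world directions of the voxel axes."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3 vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all axes")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 per axis")
        if self.direction.shape != (3, 3) or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-8
        ):
            raise ValueError("direction must be a 3x3 orthonormal matrix")

    # ---- coordinate transforms -------------------------------------------

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world points (mm) to continuous voxel coordinates.

        Accepts a single point ``(3,)`` or an array ``(..., 3)``.  Points
        outside the grid simply map to coordinates outside
        ``[0, dims-1]``; no clipping is applied.
        """
        p = np.asarray(points, dtype=float)
        local = (p - self.origin) @ self.direction  # == direction.T applied to rows
        return local / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map continuous voxel coordinates to world points (mm)."""
        idx = np.asarray(indices, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    # ---- bounding geometry ------------------------------------------------

    def local_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box of the voxel slabs in the grid's local frame (mm),
        relative to the origin: ``[-spacing/2, (dims-1)*spacing + spacing/2]``."""
        lo = -self.spacing / 2.0
        hi = (np.array(self.dims) - 1) * self.spacing + self.spacing / 2.0
        return lo, hi

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grid3D):
            return NotImplemented
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.direction, other.direction, atol=1e-9)
        )


def _check_frames(grid: Grid3D, frames) -> list[np.ndarray]:
    out = []
    for f in frames:
        a = np.asarray(f)
        if a.shape != grid.dims:
            raise ValueError(f"frame shape {a.shape} does not match grid dims {grid.dims}")
        out.append(a)
    if not out:
        raise ValueError("at least one frame required")
    return out


@dataclass
class ScalarVolume:
    """Image source (CT, PET, ...) with one frame per time bin."""

    grid: Grid3D
    frames: list[np.ndarray]
    modality: str = "other"
    units: str = "arbitrary"
    name: str = ""

    def __post_init__(self):
        self.frames = _check_frames(self.grid, self.frames)

    @property
    def n_bins(self) -> int:
        return len(self.frames)

    def frame(self, t: int) -> np.ndarray:
        """Frame for time bin ``t``; static volumes (one frame) ignore ``t``."""
        if self.n_bins == 1:
            return self.frames[0]
        if not 0 <= t < self.n_bins:
            raise IndexError(f"time bin {t} out of range [0, {self.n_bins})")
        return self.frames[t]

    def sample(self, points: np.ndarray, t: int = 0):
        """Trilinear interpolation of frame ``t`` at world points.

        Returns ``(values, outside)`` where ``outside`` flags points outside
        the grid's bounding box; outside points get the value 0.
        """
        return sample_trilinear(self, points, t)


@dataclass
class BinaryVolume:
    """Delineation (target/OAR/margin) as a {0,1} volume; temporal
    delineations carry one frame per bin."""

    grid: Grid3D
    frames: list[np.ndarray]
    name: str = ""
    color: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 1.0)

    def __post_init__(self):
        self.frames = [np.asarray(f) for f in self.frames]
        for f in self.frames:
            vals = np.unique(f)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary volume values must be in {0, 1}")
        self.frames = _check_frames(self.grid, [f.astype(np.uint8) for f in self.frames])

    @property
    def n_bins(self) -> int:
        return len(self.frames)

    def frame(self, t: int = 0) -> np.ndarray:
        if self.n_bins == 1:
            return self.frames[0]
        if not 0 <= t < self.n_bins:
            raise IndexError(f"time bin {t} out of range [0, {self.n_bins})")
        return self.frames[t]

    def contains(self, points: np.ndarray, t: int = 0) -> np.ndarray:
        """Nearest-neighbour membership test at world points (masks are
        categorical; interpolation would invent geometry)."""
        idx = np.rint(self.grid.world_to_voxel(points)).astype(int)
        dims = np.array(self.grid.dims)
        inside_grid = np.all((idx >= 0) & (idx < dims), axis=-1)
        idx_c = np.clip(idx, 0, dims - 1)
        f = self.frame(t)
        member = f[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]].astype(bool)
        return member & inside_grid

    def indicator(self, points: np.ndarray, t: int = 0):
        """Trilinearly interpolated {0,1} indicator — the smooth field whose
        0.5 level set is the rendered delineation surface."""
        vol = ScalarVolume(self.grid, [f.astype(float) for f in self.frames])
        return vol.sample(points, t if self.n_bins > 1 else 0)


@dataclass
class DoseVolume:
    """Static 3D dose distribution in Gy."""

    grid: Grid3D
    values: np.ndarray = None
    name: str = "dose"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError("dose array shape must match grid dims")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0 Gy")

    def sample(self, points: np.ndarray):
        vol = ScalarVolume(self.grid, [self.values], units="Gy")
        return vol.sample(points, 0)


# ---------------------------------------------------------------------------
# Sampling


def sample_trilinear(vol: ScalarVolume, points: np.ndarray, t: int = 0):
    """Trilinear interpolation of ``vol``'s frame ``t`` at world points (mm).

    Points outside the volume's bounding box return 0 and are flagged in the
    ``outside`` array.  Between the outermost voxel centres and the box edge,
    values are edge-clamped.
    """
    if vol.n_bins > 1 and not 0 <= t < vol.n_bins:
        raise IndexError(f"time bin {t} out of range [0, {vol.n_bins})")
    frame = vol.frame(t)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    squeeze = np.asarray(points).ndim == 1

    c = vol.grid.world_to_voxel(p)
    dims = np.array(vol.grid.dims)
    outside = np.any((c < -0.5) | (c >= dims - 0.5), axis=-1)

    cc = np.clip(c, 0.0, dims - 1.0)
    i0 = np.floor(cc).astype(int)
    i0 = np.minimum(i0, dims - 2)
    i0 = np.maximum(i0, 0)
    frac = cc - i0
    # degenerate axes (dims == 1): everything collapses to index 0
    for ax in range(3):
        if dims[ax] == 1:
            i0[:, ax] = 0
            frac[:, ax] = 0.0
    i1 = np.minimum(i0 + 1, dims - 1)

    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]
    fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]

    v = (
        frame[x0, y0, z0] * (1 - fx) * (1 - fy) * (1 - fz)
        + frame[x1, y0, z0] * fx * (1 - fy) * (1 - fz)
        + frame[x0, y1, z0] * (1 - fx) * fy * (1 - fz)
        + frame[x0, y0, z1] * (1 - fx) * (1 - fy) * fz
        + frame[x1, y1, z0] * fx * fy * (1 - fz)
        + frame[x1, y0, z1] * fx * (1 - fy) * fz
        + frame[x0, y1, z1] * (1 - fx) * fy * fz
        + frame[x1, y1, z1] * fx * fy * fz
    ).astype(float)
    v[outside] = 0.0
    if squeeze:
        return v[0], bool(outside[0])
    return v, outside


# ---------------------------------------------------------------------------
# Transfer functions


@dataclass(frozen=True)
class WindowLevel:
    """Display window: intensities <= lower are transparent, >= upper are at
    full (capped) opacity."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("window lower bound must be < upper bound")


class TransferFunction:
    """Piecewise-linear map from voxel value to RGBA.

    Control-point values must be strictly increasing and every opacity must
    respect the opacity cap.  Evaluation clamps to the first/last control
    point outside the covered range.
    """

    def __init__(self, values, colors, cap: float = 1.0):
        values = np.asarray(values, dtype=float)
        colors = np.asarray(colors, dtype=float)
        if not 0.0 <= cap <= 1.0:
            raise ValueError("opacity cap must be in [0, 1]")
        if values.ndim != 1 or colors.shape != (values.size, 4):
            raise ValueError("need N control values and N RGBA colors")
        if values.size < 1:
            raise ValueError("at least one control point required")
        if np.any(np.diff(values) <= 0):
            raise ValueError("control-point values must be strictly increasing")
        if np.any(colors[:, 3] < 0) or np.any(colors[:, 3] > cap + 1e-12):
            raise ValueError(f"opacities must lie in [0, cap={cap}]")
        self.values = values
        self.colors = colors
        self.cap = float(cap)

    def __call__(self, v: np.ndarray) -> np.ndarray:
        """Evaluate at values ``v`` -> RGBA array of shape ``v.shape + (4,)``."""
        v = np.asarray(v, dtype=float)
        out = np.empty(v.shape + (4,))
        for ch in range(4):
            out[..., ch] = np.interp(v, self.values, self.colors[:, ch])
        return out


def tf_from_window(w: WindowLevel, cap: float, color) -> TransferFunction:
    """Windowing-coupled transfer function: transparent at or below the lower
    window value, constant opacity ``cap`` at or above the upper value, with
    a linear opacity ramp in between.  The colour is constant."""
    color = np.asarray(color, dtype=float)
    if color.shape != (3,):
        raise ValueError("color must be RGB")
    if not 0.0 <= cap <= 1.0:
        raise ValueError("opacity cap must be in [0, 1]")
    vals = [w.lower, w.upper]
    cols = [[*color, 0.0], [*color, cap]]
    return TransferFunction(vals, cols, cap=cap)


# ---------------------------------------------------------------------------
# Cropping


def crop_to_content(b: BinaryVolume) -> BinaryVolume:
    """Tight axis-aligned crop to the union of nonzero voxels over all
    frames, keeping world positions unchanged (origin is shifted).

    Mirrors the memory-reduction step applied to rasterized delineations:
    only the minimal sub-volume holding the segmentation is kept.
    """
    union = np.zeros(b.grid.dims, dtype=bool)
    for f in b.frames:
        union |= f.astype(bool)
    if not union.any():
        raise ValueError("empty structure: cannot crop an all-zero volume")
    nz = np.nonzero(union)
    lo = np.array([a.min() for a in nz])
    hi = np.array([a.max() for a in nz])
    new_origin = b.grid.voxel_to_world(lo.astype(float))
    new_grid = Grid3D(new_origin, b.grid.spacing, tuple(hi - lo + 1), b.grid.direction)
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    new_frames = [f[sl].copy() for f in b.frames]
    return BinaryVolume(new_grid, new_frames, name=b.name, color=b.color)
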