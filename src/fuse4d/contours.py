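"""Structure sets: planar contours, DICOM-RTSS / JSON dialect I/O, and
rasterization to binary volumes.

Rasterization follows the clinical conversion path: each planar contour is
assigned to the nearest slice of the target grid (typically the planning CT)
and filled with an even-odd (parity) rule tested at voxel centres, so nested
contours produce holes and the result is deterministic.  Voxel centres that
fall exactly on a contour edge count as inside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import BinaryVolume, Grid3D

__all__ = [
    "PlanarContour",
    "Structure",
    "StructureSet",
    "read_structure_set",
    "write_structure_set_json",
    "write_structure_set_dicom",
    "rasterize",
    "majority_vote",
    "points_in_polygon",
]


@dataclass
class PlanarContour:
    """One closed planar polygon at axial position ``z`` (mm); vertices are
    (x, y) points in mm, implicitly closed."""

    z: float
    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("a planar contour needs >= 3 (x, y) vertices")
        if _self_intersects(self.vertices):
            warnings.warn("contour polygon is self-intersecting", stacklevel=2)


def _cross2(ax, ay, bx, by):
    return ax * by - ay * bx


def _self_intersects(v: np.ndarray) -> bool:
    """Proper-crossing test between all non-adjacent edge pairs, vectorized
    over the second edge."""
    n = len(v)
    p = v
    q = np.roll(v, -1, axis=0)
    for i in range(n - 2):
        j = np.arange(i + 2, n - 1 if i == 0 else n)
        p1, p2 = p[i], q[i]
        p3, p4 = p[j], q[j]
        e34 = p4 - p3
        e12 = p2 - p1
        d1 = _cross2(e34[:, 0], e34[:, 1], p1[0] - p3[:, 0], p1[1] - p3[:, 1])
        d2 = _cross2(e34[:, 0], e34[:, 1], p2[0] - p3[:, 0], p2[1] - p3[:, 1])
        d3 = _cross2(e12[0], e12[1], p3[:, 0] - p1[0], p3[:, 1] - p1[1])
        d4 = _cross2(e12[0], e12[1], p4[:, 0] - p1[0], p4[:, 1] - p1[1])
        if np.any(((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0))):
            return True
    return False


@dataclass
class Structure:
    name: str
    contours: list[list[PlanarContour]]  # one list per time bin
    color: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 1.0)
    role: str = "target"  # target | oar | margin

    def __post_init__(self):
        if not any(len(bin_contours) for bin_contours in self.contours):
            raise ValueError(f"structure {self.name!r} has no contours in any bin")

    @property
    def n_bins(self) -> int:
        return len(self.contours)

    def bin(self, t: int) -> list[PlanarContour]:
        if self.n_bins == 1:
            return self.contours[0]
        if not 0 <= t < self.n_bins:
            raise IndexError(f"time bin {t} out of range [0, {self.n_bins})")
        return self.contours[t]


@dataclass
class StructureSet:
    """Named structures, each a stack of planar contours per time bin, all in
    world mm in one frame of reference."""

    structures: dict[str, Structure] = field(default_factory=dict)
    frame_of_reference: str = ""

    def __post_init__(self):
        if not self.structures:
            raise ValueError("empty structure set")

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def names(self) -> list[str]:
        return list(self.structures)


# ---------------------------------------------------------------------------
# JSON dialect
#
# Schema (documented in docs/contour_schema.md):
# {
#   "frame_of_reference": "<uid or free text>",
#   "structures": [
#     {"name": "...", "color": [r, g, b, a], "role": "target",
#      "bins": [                       # one entry per time bin
#         [{"z": <mm>, "points": [[x, y], ...]}, ...],
#      ]}
#   ]
# }


def _structure_set_to_dict(ss: StructureSet) -> dict:
    return {
        "frame_of_reference": ss.frame_of_reference,
        "structures": [
            {
                "name": s.name,
                "color": list(s.color),
                "role": s.role,
                "bins": [
                    [{"z": c.z, "points": c.vertices.tolist()} for c in bin_contours]
                    for bin_contours in s.contours
                ],
            }
            for s in ss.structures.values()
        ],
    }


def _structure_set_from_dict(d: dict) -> StructureSet:
    structures = {}
    for sd in d.get("structures", []):
        contours = [
            [PlanarContour(float(c["z"]), np.asarray(c["points"], dtype=float)) for c in b]
            for b in sd["bins"]
        ]
        s = Structure(
            name=sd["name"],
            contours=contours,
            color=tuple(sd.get("color", (1, 0, 0, 1))),
            role=sd.get("role", "target"),
        )
        structures[s.name] = s
    if not structures:
        raise ValueError("empty structure set")
    return StructureSet(structures, frame_of_reference=d.get("frame_of_reference", ""))


def write_structure_set_json(ss: StructureSet, path) -> None:
    Path(path).write_text(json.dumps(_structure_set_to_dict(ss), indent=1))


def read_structure_set(path, dialect: str = None) -> StructureSet:
    """Read a structure set from DICOM-RTSS or the JSON contour dialect.

    The dialect is inferred from the file when not given (.json -> json,
    anything else is tried as DICOM).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure set file not found: {path}")
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "dicom-rtss"
    if dialect == "json":
        return _structure_set_from_dict(json.loads(path.read_text()))
    if dialect == "dicom-rtss":
        return _read_rtss(path)
    raise ValueError(f"unknown structure-set dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# DICOM-RT Structure Set


def _read_rtss(path) -> StructureSet:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise ValueError(f"{path} is not an RT Structure Set")
    for_uid = ""
    if "ReferencedFrameOfReferenceSequence" in ds and len(ds.ReferencedFrameOfReferenceSequence):
        for_uid = str(ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID)
    elif "StructureSetROISequence" in ds and len(ds.StructureSetROISequence):
        for_uid = str(
            getattr(ds.StructureSetROISequence[0], "ReferencedFrameOfReferenceUID", "")
        )
    if not for_uid:
        raise ValueError("RTSS is missing frame-of-reference linkage")

    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)

    structures = {}
    for rc in ds.ROIContourSequence:
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI-{number}")
        color = tuple(np.array(getattr(rc, "ROIDisplayColor", [255, 0, 0]), float) / 255.0) + (
            1.0,
        )
        contours = []
        for cs in getattr(rc, "ContourSequence", []):
            pts = np.asarray(cs.ContourData, dtype=float).reshape(-1, 3)
            contours.append(PlanarContour(float(pts[0, 2]), pts[:, :2]))
        if contours:
            structures[name] = Structure(name, [contours], color=color)
    if not structures:
        raise ValueError("empty structure set")
    return StructureSet(structures, frame_of_reference=for_uid)


def write_structure_set_dicom(ss: StructureSet, path) -> None:
    """Write the (static, bin-0) contours of a structure set as a minimal
    DICOM-RT Structure Set."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "fuse4d"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"

    for_uid = ss.frame_of_reference or str(generate_uid())
    ref_for = Dataset()
    ref_for.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_for]

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, s in enumerate(ss.structures.values(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "MANUAL"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ROIDisplayColor = [int(round(c * 255)) for c in s.color[:3]]
        rc.ContourSequence = []
        for c in s.bin(0):
            cd = Dataset()
            cd.ContourGeometricType = "CLOSED_PLANAR"
            cd.NumberOfContourPoints = len(c.vertices)
            data = np.column_stack([c.vertices, np.full(len(c.vertices), c.z)])
            cd.ContourData = [f"{v:.6f}" for v in data.ravel()]
            rc.ContourSequence.append(cd)
        ds.ROIContourSequence.append(rc)

    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Rasterization


def points_in_polygon(points: np.ndarray, polygon: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Even-odd (parity) point-in-polygon test; points on an edge count as
    inside (deterministic tie-break).

    ``points``: (N, 2); ``polygon``: (M, 2), implicitly closed.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # parity toggle: edge straddles the horizontal line through the point
        straddle = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddle & (x < x_cross)
        # boundary test: point within atol of the segment
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            on_edge |= np.hypot(x - x1, y - y1) <= atol
            continue
        u = ((x - x1) * dx + (y - y1) * dy) / seg_len2
        u = np.clip(u, 0.0, 1.0)
        on_edge |= np.hypot(x - (x1 + u * dx), y - (y1 + u * dy)) <= atol
    return inside | on_edge


def rasterize(ss: StructureSet, name: str, grid: Grid3D, t: int = 0) -> BinaryVolume:
    """Rasterize one structure's time-bin ``t`` contours onto ``grid``.

    A voxel is foreground iff its centre lies inside the parity-filled union
    of the contours assigned to its slice; each contour goes to the nearest
    slice centre in z (within half a slice spacing, farther is an error).
    """
    if name not in ss.structures:
        raise KeyError(f"structure {name!r} not in set (have {ss.names()})")
    if not np.allclose(grid.direction, np.eye(3)):
        raise ValueError("rasterization requires an axis-aligned (identity-direction) grid")
    contours = ss[name].bin(t)
    if not contours:
        raise ValueError(f"structure {name!r} has no contours in bin {t}")

    nx, ny, nz = grid.dims
    slice_z = grid.origin[2] + np.arange(nz) * grid.spacing[2]
    tol = grid.spacing[2] / 2.0 + 1e-9
    by_slice: dict[int, list[PlanarContour]] = {}
    for c in contours:
        k = int(np.argmin(np.abs(slice_z - c.z)))
        if abs(slice_z[k] - c.z) > tol:
            raise ValueError(
                f"contour at z={c.z:.3f} mm is farther than half a slice spacing "
                f"from every slice centre of the grid"
            )
        by_slice.setdefault(k, []).append(c)
    if not by_slice:
        raise ValueError(f"structure {name!r} has no contour near any slice")

    # voxel-centre xy coordinates of one slice
    xs = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    mask = np.zeros(grid.dims, dtype=np.uint8)
    for k, slice_contours in by_slice.items():
        # parity across all contours of the slice: nested contours open holes
        parity = np.zeros(len(centers), dtype=int)
        boundary = np.zeros(len(centers), dtype=bool)
        for c in slice_contours:
            inside_one = points_in_polygon(centers, c.vertices)
            on_b = _on_polygon_boundary(centers, c.vertices)
            parity += (inside_one & ~on_b).astype(int)
            boundary |= on_b
        mask[:, :, k] = ((parity % 2 == 1) | boundary).reshape(nx, ny).astype(np.uint8)
    s = ss[name]
    return BinaryVolume(grid, [mask], name=name, color=s.color)


def _on_polygon_boundary(points: np.ndarray, polygon: np.ndarray, atol: float = 1e-9):
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            on_edge |= np.hypot(x - x1, y - y1) <= atol
            continue
        u = np.clip(((x - x1) * dx + (y - y1) * dy) / seg_len2, 0.0, 1.0)
        on_edge |= np.hypot(x - (x1 + u * dx), y - (y1 + u * dy)) <= atol
    return on_edge


# ---------------------------------------------------------------------------
# Majority vote


def majority_vote(masks: list[BinaryVolume], k: int) -> BinaryVolume:
    """Consensus mask: a voxel is foreground iff at least ``k`` of the input
    masks are foreground there (e.g. 3-of-4 physician delineations).

    All masks must share one grid; multi-bin masks are voted frame-wise.
    """
    if not masks:
        raise ValueError("need at least one mask")
    if k < 1 or k > len(masks):
        raise ValueError(f"k={k} must be in [1, {len(masks)}]")
    grid = masks[0].grid
    n_bins = masks[0].n_bins
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("majority vote requires masks on identical grids")
        if m.n_bins != n_bins:
            raise ValueError("majority vote requires equal frame counts")
    frames = []
    for t in range(n_bins):
        count = np.zeros(grid.dims, dtype=int)
        for m in masks:
            count += m.frames[t]
        frames.append((count >= k).astype(np.uint8))
    return BinaryVolume(grid, frames, name=f"majority-{k}of{len(masks)}")
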