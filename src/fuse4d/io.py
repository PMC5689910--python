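"""Volume I/O: NIfTI files, DICOM series, and per-bin 4D manifests.

The world frame of a loaded volume is the affine frame of the file (NIfTI)
or the DICOM patient frame (SimpleITK); the toolkit never converts between
the two, it only requires that all sources of one scene share a frame of
reference.  Only orthonormal (possibly flipped/permuted/rotated) affines are
accepted — sheared grids are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .volume import BinaryVolume, DoseVolume, Grid3D, ScalarVolume

__all__ = [
    "read_volume",
    "read_binary_volume",
    "read_dose_volume",
    "write_nifti",
    "read_4d_manifest",
    "write_4d_manifest",
]


def _grid_from_affine(affine: np.ndarray, dims) -> Grid3D:
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero-length axis")
    direction = M / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
        raise ValueError("sheared affines are not supported (direction must be orthonormal)")
    # re-orthonormalize to machine precision
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return Grid3D(affine[:3, 3], spacing, tuple(int(d) for d in dims), direction)


def _affine_from_grid(grid: Grid3D) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.direction * grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _read_array_grid(path) -> tuple[np.ndarray, Grid3D]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        return data, _grid_from_affine(img.affine, data.shape)
    if path.is_dir():
        return _read_dicom_series(path)
    raise ValueError(f"unsupported volume format: {path}")


def _read_dicom_series(directory) -> tuple[np.ndarray, Grid3D]:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK array is (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    origin = np.array(img.GetOrigin())
    spacing = np.array(img.GetSpacing())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    grid = Grid3D(origin, spacing, data.shape, direction)
    return data, grid


def _stem(path) -> str:
    name = Path(path).name
    for suffix in (".nii.gz", ".nii"):
        if name.lower().endswith(suffix):
            return name[: -len(suffix)]
    return Path(path).stem


def read_volume(path, modality: str = "other", units: str = "arbitrary") -> ScalarVolume:
    """Read a static 3D image volume (NIfTI file or DICOM series directory)."""
    data, grid = _read_array_grid(path)
    return ScalarVolume(grid, [data], modality=modality, units=units, name=_stem(path))


def read_binary_volume(path, name: str = None, threshold: float = 0.5) -> BinaryVolume:
    """Read a delineation mask; values are binarized at ``threshold``."""
    data, grid = _read_array_grid(path)
    return BinaryVolume(
        grid, [(data > threshold).astype(np.uint8)], name=name or _stem(path)
    )


def read_dose_volume(path) -> DoseVolume:
    """Read a 3D dose volume (values in Gy)."""
    data, grid = _read_array_grid(path)
    return DoseVolume(grid, np.maximum(data, 0.0))


def write_nifti(path, array: np.ndarray, grid: Grid3D) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine_from_grid(grid))
    nib.save(img, str(path))


def write_4d_manifest(path, bin_files: list[str], extra: dict = None) -> None:
    """Write a JSON manifest listing per-bin volume files in bin order."""
    d = {"bins": list(bin_files)}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1))


def read_4d_manifest(path, modality: str = "other") -> ScalarVolume:
    """Read a 4D volume stored as one file per time bin plus a JSON manifest
    with the bin order (key ``"bins"``)."""
    path = Path(path)
    d = json.loads(path.read_text())
    files = d.get("bins")
    if not files:
        raise ValueError(f"{path}: manifest lists no bins")
    frames = []
    grid = None
    for f in files:
        data, g = _read_array_grid(path.parent / f)
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"{f}: all bins of a 4D volume must share one grid")
        frames.append(data)
    return ScalarVolume(grid, frames, modality=modality, name=path.stem)
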