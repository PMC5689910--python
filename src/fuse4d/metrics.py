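"""Contour-quality metrics: Dice coefficient, Hausdorff distance variants,
inter-rater conformity index and acceptance decisions.

Both masks must live on one grid (the caller rasterizes/maps everything onto
the planning grid first — comparisons are made in the planning frame, never
by resampling one mask onto the other).  Surface voxels are foreground
voxels with at least one background 6-neighbour, the grid border counting as
background; distances are Euclidean mm between surface voxel centres, so
anisotropic spacings are respected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .volume import BinaryVolume

__all__ = [
    "MetricsReport",
    "RatingSet",
    "dice",
    "surface_distances",
    "hausdorff_stats",
    "conformity_index",
    "acceptance_decision",
    "assess",
]

_STRUCT6 = np.array(
    [
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
    ],
    dtype=bool,
)


@dataclass
class MetricsReport:
    """Dice and Hausdorff statistics of one mask pair, plus bookkeeping."""

    dice: float
    hd_avg: float
    hd_max: float
    hd_95: float
    n_voxels_a: int
    n_voxels_b: int
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("Dice coefficient must be in [0, 1]")
        if not 0.0 <= self.hd_avg <= self.hd_95 + 1e-9 or self.hd_95 > self.hd_max + 1e-9:
            raise ValueError("expected hd_avg <= hd_95 <= hd_max, all >= 0")

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hd_avg_mm": self.hd_avg,
            "hd_max_mm": self.hd_max,
            "hd_95_mm": self.hd_95,
            "n_voxels_test": self.n_voxels_a,
            "n_voxels_reference": self.n_voxels_b,
            "spacing_mm": list(self.spacing),
        }


@dataclass
class RatingSet:
    """Per-case quality ratings (1 = excellent .. 5 = poor) for two raters,
    with optional per-case certainty flags."""

    rater1: np.ndarray
    rater2: np.ndarray
    certain1: np.ndarray = None
    certain2: np.ndarray = None

    def __post_init__(self):
        self.rater1 = np.asarray(self.rater1, dtype=int)
        self.rater2 = np.asarray(self.rater2, dtype=int)
        if self.rater1.shape != self.rater2.shape or self.rater1.ndim != 1:
            raise ValueError("the two rating vectors must be equal-length 1-D")
        for r in (self.rater1, self.rater2):
            if r.size and (r.min() < 1 or r.max() > 5):
                raise ValueError("ratings must be integers in 1..5")
        if self.certain1 is None:
            self.certain1 = np.ones_like(self.rater1, dtype=bool)
        if self.certain2 is None:
            self.certain2 = np.ones_like(self.rater2, dtype=bool)


def _same_grid(a: BinaryVolume, b: BinaryVolume):
    if a.grid != b.grid:
        raise ValueError(
            "masks must share one grid; rasterize/map both onto the planning grid first"
        )


def dice(a: BinaryVolume, b: BinaryVolume, t: int = 0) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two masks on one grid."""
    _same_grid(a, b)
    fa = a.frame(t).astype(bool)
    fb = b.frame(t).astype(bool)
    na, nb = int(fa.sum()), int(fb.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty; Dice is undefined")
    return 2.0 * int((fa & fb).sum()) / (na + nb)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background 6-neighbour; the border of the
    grid counts as background (border_value=0)."""
    fg = mask.astype(bool)
    eroded = binary_erosion(fg, structure=_STRUCT6, border_value=0)
    return fg & ~eroded


def surface_distances(a: BinaryVolume, b: BinaryVolume, t: int = 0):
    """Directed surface-to-surface distance samples (mm): for every surface
    voxel centre of one mask, the Euclidean distance to the nearest surface
    voxel centre of the other.  Returns ``(d_ab, d_ba)``."""
    _same_grid(a, b)
    sa = _surface_voxels(a.frame(t))
    sb = _surface_voxels(b.frame(t))
    if not sa.any() or not sb.any():
        raise ValueError("both masks must be nonempty")
    spacing = a.grid.spacing
    pa = np.argwhere(sa) * spacing
    pb = np.argwhere(sb) * spacing
    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)
    d_ab, _ = tree_b.query(pa)
    d_ba, _ = tree_a.query(pb)
    return d_ab, d_ba


def hausdorff_stats(a: BinaryVolume, b: BinaryVolume, t: int = 0) -> dict:
    """Maximum, average and 95th-percentile Hausdorff distances (mm).

    All three statistics are computed on the pooled (symmetrized) directed
    distance lists; the percentile uses linear interpolation.
    """
    d_ab, d_ba = surface_distances(a, b, t)
    pooled = np.concatenate([d_ab, d_ba])
    return {
        "hd_max": float(pooled.max()),
        "hd_avg": float(pooled.mean()),
        "hd_95": float(np.percentile(pooled, 95)),
    }


def assess(test: BinaryVolume, reference: BinaryVolume, t: int = 0) -> MetricsReport:
    """Full quality assessment of a test delineation against a reference
    (e.g. an ITV against the planning ITV)."""
    d = dice(test, reference, t)
    hd = hausdorff_stats(test, reference, t)
    return MetricsReport(
        dice=d,
        hd_avg=hd["hd_avg"],
        hd_max=hd["hd_max"],
        hd_95=hd["hd_95"],
        n_voxels_a=int(test.frame(t).sum()),
        n_voxels_b=int(reference.frame(t).sum()),
        spacing=tuple(test.grid.spacing),
    )


def conformity_index(r: RatingSet) -> float:
    """Inter-rater conformity index: the mean absolute difference between
    the two raters' ratings over all cases.  Lower means more consistent."""
    if r.rater1.size == 0:
        raise ValueError("empty rating set")
    return float(np.mean(np.abs(r.rater1 - r.rater2)))


def acceptance_decision(rating: int) -> bool:
    """A delineation is accepted iff its rating is at most 3 (acceptable);
    ratings above 3 are rejected."""
    rating = int(rating)
    if not 1 <= rating <= 5:
        raise ValueError("rating must be an integer in 1..5")
    return rating <= 3
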