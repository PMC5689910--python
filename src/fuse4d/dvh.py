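"""Cumulative dose-volume histograms and summary statistics.

Mask membership is evaluated at dose-grid voxel centres (nearest-neighbour
lookup when the mask lives on a different grid), with no partial-volume
weighting — a documented bias for very small structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BinaryVolume, DoseVolume

__all__ = ["DVHCurve", "cumulative_dvh", "dvh_stats", "in_mask_doses"]

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving at least each
    dose level, evaluated at the bin edges."""

    edges_gy: np.ndarray
    fractions: np.ndarray
    structure: str
    volume_mm3: float

    def __post_init__(self):
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.edges_gy.shape != self.fractions.shape:
            raise ValueError("edges and fractions must align")
        if abs(self.fractions[0] - 1.0) > 1e-12:
            raise ValueError("cumulative DVH must start at fraction 1 for dose 0")
        if np.any(np.diff(self.fractions) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def fraction_at(self, dose_gy: float) -> float:
        """Exact cumulative fraction at an arbitrary dose (recomputed from the
        curve by step lookup: fraction of the nearest edge at or below)."""
        i = int(np.searchsorted(self.edges_gy, dose_gy, side="right")) - 1
        i = max(i, 0)
        return float(self.fractions[i])


def in_mask_doses(dose: DoseVolume, mask: BinaryVolume, t: int = 0) -> np.ndarray:
    """Dose samples (Gy) of all dose-grid voxels whose centre lies in the
    mask."""
    if mask.grid == dose.grid:
        member = mask.frame(t).astype(bool)
    else:
        idx = np.indices(dose.grid.dims).reshape(3, -1).T.astype(float)
        pts = dose.grid.voxel_to_world(idx)
        member = mask.contains(pts, t).reshape(dose.grid.dims)
    doses = dose.values[member]
    if doses.size == 0:
        raise ValueError("mask is empty after mapping onto the dose grid")
    return doses


def cumulative_dvh(
    dose: DoseVolume,
    mask: BinaryVolume,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    t: int = 0,
) -> DVHCurve:
    """Cumulative DVH of a structure: fraction(d) = (# in-mask voxels with
    dose >= d) / (# in-mask voxels), evaluated at bin edges 0 .. max dose."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0 Gy")
    doses = in_mask_doses(dose, mask, t)
    d_max = float(doses.max())
    n_bins = int(np.ceil(d_max / bin_width_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    # count of doses >= each edge, via descending sorted search
    sorted_d = np.sort(doses)
    counts = doses.size - np.searchsorted(sorted_d, edges, side="left")
    fractions = counts / doses.size
    n_in_mask = doses.size
    # absolute volume is reported on the dose grid (membership grid)
    volume = n_in_mask * dose.grid.voxel_volume()
    return DVHCurve(edges, fractions, structure=mask.name, volume_mm3=volume)


def dvh_stats(
    doses: np.ndarray,
    v_levels_gy=(),
    d_levels_pct=(),
) -> dict:
    """Summary statistics from raw in-mask voxel doses.

    * ``Dmin/Dmax/Dmean``: extreme and mean voxel doses (Gy).
    * ``V_x``: fraction of the structure receiving at least x Gy.
    * ``D_x%``: smallest dose received by at least x% of the structure
      (lower-interpolation quantile at 1 - x/100).
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose sample")
    out = {
        "Dmin": float(doses.min()),
        "Dmax": float(doses.max()),
        "Dmean": float(doses.mean()),
    }
    for x in v_levels_gy:
        out[f"V_{x:g}Gy"] = float(np.mean(doses >= x))
    for x in d_levels_pct:
        if not 0 < x <= 100:
            raise ValueError("D_x% levels must be percentages in (0, 100]")
        out[f"D_{x:g}%"] = float(np.quantile(doses, 1.0 - x / 100.0, method="lower"))
    return out
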