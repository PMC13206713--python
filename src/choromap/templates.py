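"""Fovea-centred spatial templates for the 60x60 macular grid.

Three templates are provided, all defined on fovea-centred coordinates in
micrometres (x increasing toward the temporal side for a right eye, y
increasing superiorly):

* a 60x60 square grid of 120 um cells covering 7200 x 7200 um;
* the ETDRS template (1/3/6-mm diameter rings split into quadrants), extended
  with a near-periphery ring beyond the 6-mm circle;
* radial eccentricity bins of 0.05 mm, matching the grid resolution.

Cell membership is decided by cell-centre coordinates, so every cell receives
exactly one grid index, one sector label and one eccentricity bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

GRID_SPAN_UM = 7200.0
CELL_UM = 120.0
N_CELLS = 60

#: Sentinel returned for coordinates outside the analysed square.
OUTSIDE = -1

# ETDRS ring boundaries (radii, um): central 1-mm disc, inner 3-mm ring,
# outer 6-mm ring, near periphery beyond.
RING_EDGES_UM = (500.0, 1500.0, 3000.0)
RINGS = ("central", "inner", "outer", "near_periphery")
QUADRANTS = ("temporal", "superior", "nasal", "inferior")


@dataclass(frozen=True)
class SectorLabel:
    """ETDRS sector: a ring and (outside the central disc) a quadrant."""

    ring: str
    quadrant: str  # "none" for the central disc

    def __str__(self) -> str:  # e.g. "outer_temporal", "central"
        return self.ring if self.quadrant == "none" else f"{self.ring}_{self.quadrant}"


#: The 13 realizable sector labels (1 central + 4 inner + 4 outer + 4 near-periphery).
ALL_SECTORS = tuple(
    [SectorLabel("central", "none")]
    + [SectorLabel(r, q) for r in RINGS[1:] for q in QUADRANTS]
)


def grid_index(x_um, y_um):
    """Map fovea-centred coordinates (um) to (row, col) of the 60x60 grid.

    Cells are half-open: ``index = floor((coord + 3600) / 120)``. The row
    index follows x (along a B-scan), the column index follows y (across
    B-scans). Out-of-range coordinates yield :data:`OUTSIDE` (-1). Accepts
    scalars or arrays.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    row = np.floor((x + GRID_SPAN_UM / 2) / CELL_UM).astype(int)
    col = np.floor((y + GRID_SPAN_UM / 2) / CELL_UM).astype(int)
    bad_c = (col < 0) | (col >= N_CELLS)
    bad_r = (row < 0) | (row >= N_CELLS)
    col = np.where(bad_c, OUTSIDE, col)
    row = np.where(bad_r, OUTSIDE, row)
    if np.isscalar(x_um) and np.isscalar(y_um):
        return int(row), int(col)
    return row, col


def _quadrant(x_um: float, y_um: float) -> str:
    """Quadrant for a right (OD) eye; boundaries on the 45-degree diagonals.

    A point exactly on a diagonal is assigned to the clockwise-following
    quadrant (e.g. the 45-degree ray belongs to temporal).
    """
    theta = np.degrees(np.arctan2(y_um, x_um))  # (-180, 180]
    if -45.0 < theta <= 45.0:
        return "temporal"
    if 45.0 < theta <= 135.0:
        return "superior"
    if -135.0 < theta <= -45.0:
        return "inferior"
    return "nasal"


def etdrs_sector(x_um: float, y_um: float, laterality: str = "OD") -> SectorLabel:
    """ETDRS sector label for a fovea-centred point.

    Rings are half-open annuli at radii [0, 500), [500, 1500), [1500, 3000)
    and [3000, inf) um. For left (OS) eyes the horizontal axis is mirrored so
    that nasal/temporal labels are anatomic.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    if laterality == "OS":
        x_um = -x_um
    r = float(np.hypot(x_um, y_um))
    if r < RING_EDGES_UM[0]:
        return SectorLabel("central", "none")
    if r < RING_EDGES_UM[1]:
        ring = "inner"
    elif r < RING_EDGES_UM[2]:
        ring = "outer"
    else:
        ring = "near_periphery"
    return SectorLabel(ring, _quadrant(x_um, y_um))


def eccentricity_bin(r_mm, width_mm: float = 0.05):
    """Radial bin index for eccentricity ``r_mm`` (half-open bins of ``width_mm``).

    The bin centre ``(i + 0.5) * width_mm`` is the regression abscissa used
    throughout the eccentricity analyses.
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be non-negative")
    idx = np.floor(r / width_mm).astype(int)
    if np.isscalar(r_mm):
        return int(idx)
    return idx


def bin_center_mm(index, width_mm: float = 0.05):
    """Centre (mm) of eccentricity bin ``index``."""
    return (np.asarray(index) + 0.5) * width_mm


def cell_centers_um() -> tuple[np.ndarray, np.ndarray]:
    """(x, y) fovea-centred coordinates (um) of all 60x60 cell centres.

    Returns two (60, 60) arrays; the row index follows x, the column index
    follows y, matching :func:`grid_index`.
    """
    c = (np.arange(N_CELLS) + 0.5) * CELL_UM - GRID_SPAN_UM / 2
    x = np.broadcast_to(c[:, None], (N_CELLS, N_CELLS)).copy()
    y = np.broadcast_to(c[None, :], (N_CELLS, N_CELLS)).copy()
    return x, y


def cell_eccentricity_mm() -> np.ndarray:
    """(60, 60) eccentricity (mm) of every cell centre."""
    x, y = cell_centers_um()
    return np.hypot(x, y) / 1000.0


@lru_cache(maxsize=2)
def _sector_label_grid_cached(laterality: str) -> np.ndarray:
    x, y = cell_centers_um()
    out = np.empty((N_CELLS, N_CELLS), dtype=object)
    for i in range(N_CELLS):
        for j in range(N_CELLS):
            out[i, j] = str(etdrs_sector(x[i, j], y[i, j], laterality))
    return out


def sector_label_grid(laterality: str = "OD") -> np.ndarray:
    """(60, 60) array of sector label strings for every cell centre."""
    return _sector_label_grid_cached(laterality).copy()


def eccentricity_bin_grid(width_mm: float = 0.05) -> np.ndarray:
    """(60, 60) array of eccentricity bin indices for every cell centre."""
    return eccentricity_bin(cell_eccentricity_mm(), width_mm)
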