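"""Fovea-centered sectorization of thickness maps.

Three schemes: the whole macula (3 mm radius disc), the 9-sector ETDRS grid
(1 / 3 / 6 mm diameter rings split by the +-45 degree diagonals), and a
20 x 20 grid of 0.3 mm square cells over the 6 x 6 mm field.  All node
assignments are pure functions of the grid geometry.

Conventions (right-eye frame): +x nasal, +y superior.  Ring boundaries
belong to the inner region (r <= 0.5 central disc, r <= 1.5 inner ring,
r <= 3 outer ring); nodes exactly on a +-45 degree diagonal are assigned in
the fixed order nasal, superior, inferior, temporal.  The ETDRS outer ring
nominally extends to the 6 mm diameter but maps cover a 6 x 6 mm square, so
outer sectors use only nodes within the 3 mm radius circle.  A 20 x 20 cell
is retained when its center lies within that circle (316 cells); for the
inner layers (RNFL, GCIPL, INL) the central 1.2 x 1.2 mm block (16 cells) is
additionally excluded because those layers are essentially absent at the
foveal center.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .maps import DEFAULT_GRID, GridSpec, ThicknessMap

INNER_LAYERS_CENTRAL_EXCLUSION = ("RNFL", "GCIPL", "INL")
GRID20_N = 20
GRID20_CELL_MM = 0.3
ETDRS_SECTORS = ("C0", "N1", "S1", "T1", "I1", "N2", "S2", "T2", "I2")


@dataclass(frozen=True)
class SectorSummary:
    scheme: str  # whole | etdrs | grid20
    sector_id: str
    layer: str
    mean: float  # um (nan when empty/excluded)
    n_nodes: int
    excluded: bool = False
    reason: str = ""


class EmptySectorError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Geometry masks (cached per grid)

@lru_cache(maxsize=8)
def _geometry(extent_mm: float, n_nodes: int):
    grid = GridSpec(extent_mm, n_nodes)
    X, Y = grid.mesh()
    r = np.hypot(X, Y)
    disc = r <= 3.0
    # ETDRS ring index: 0 central, 1 inner, 2 outer (boundaries inward)
    ring = np.full(r.shape, -1, dtype=int)
    ring[r <= 3.0] = 2
    ring[r <= 1.5] = 1
    ring[r <= 0.5] = 0
    # quadrants with boundary priority N > S > I > T: later assignments
    # override, so the highest-priority condition is applied last
    quad = np.full(r.shape, "T", dtype="U1")
    quad[Y <= -np.abs(X)] = "I"
    quad[Y >= np.abs(X)] = "S"
    quad[np.abs(Y) <= X] = "N"
    # 20x20 cell indices: row 0 = superior (+y), col 0 = temporal (-x)
    col = np.clip(np.floor((X + 3.0) / GRID20_CELL_MM).astype(int), 0, GRID20_N - 1)
    row = np.clip(np.floor((3.0 - Y) / GRID20_CELL_MM).astype(int), 0, GRID20_N - 1)
    return grid, r, disc, ring, quad, row, col


def grid20_cell_centers() -> tuple[np.ndarray, np.ndarray]:
    """(x, y) centers of the 20 x 20 cells, shape (20, 20) indexed [row, col]."""
    cols = np.arange(GRID20_N)
    rows = np.arange(GRID20_N)
    xc = -3.0 + (cols + 0.5) * GRID20_CELL_MM
    yc = 3.0 - (rows + 0.5) * GRID20_CELL_MM
    return np.meshgrid(xc, yc)[0], np.tile(yc[:, None], (1, GRID20_N))


def grid20_retained(layer: str) -> np.ndarray:
    """Boolean (20, 20) retention mask for a layer's cells."""
    Xc, Yc = grid20_cell_centers()
    keep = np.hypot(Xc, Yc) <= 3.0
    if layer in INNER_LAYERS_CENTRAL_EXCLUSION:
        keep &= ~((np.abs(Xc) < 0.6) & (np.abs(Yc) < 0.6))
    return keep


# ---------------------------------------------------------------------------
# Scheme means

def _check_grid(tmap: ThicknessMap) -> tuple:
    n = tmap.xs.size
    extent = float(tmap.xs[-1])
    return _geometry(extent, n)


def whole_macula_mean(tmap: ThicknessMap, mask: np.ndarray | None = None) -> float:
    """Unweighted mean over non-missing grid nodes with center distance
    <= 3 mm (or over an explicit node mask)."""
    _, r, disc, *_ = _check_grid(tmap)
    use = (disc if mask is None else mask) & np.isfinite(tmap.values)
    if not use.any():
        raise EmptySectorError("no usable nodes within the 3 mm disc")
    return float(tmap.values[use].mean())


def etdrs_means(tmap: ThicknessMap) -> list[SectorSummary]:
    """Means of the 9 ETDRS sectors (empty sectors flagged, not fatal)."""
    _, r, disc, ring, quad, *_ = _check_grid(tmap)
    finite = np.isfinite(tmap.values)
    out = []
    for sector in ETDRS_SECTORS:
        if sector == "C0":
            sel = (ring == 0)
        else:
            q, ridx = sector[0], int(sector[1])
            sel = (ring == ridx) & (quad == q)
        sel = sel & finite
        n = int(sel.sum())
        if n == 0:
            out.append(SectorSummary("etdrs", sector, tmap.layer, float("nan"),
                                     0, excluded=True, reason="empty"))
        else:
            out.append(SectorSummary("etdrs", sector, tmap.layer,
                                     float(tmap.values[sel].mean()), n))
    return out


def grid20_means(tmap: ThicknessMap) -> list[SectorSummary]:
    """Means of the retained 20 x 20 cells for one layer's map."""
    _, r, disc, ring, quad, row, col = _check_grid(tmap)
    finite = np.isfinite(tmap.values)
    keep = grid20_retained(tmap.layer)
    flat = row * GRID20_N + col
    sums = np.bincount(flat[finite], weights=tmap.values[finite],
                       minlength=GRID20_N * GRID20_N).reshape(GRID20_N, GRID20_N)
    counts = np.bincount(flat[finite],
                         minlength=GRID20_N * GRID20_N).reshape(GRID20_N, GRID20_N)
    out = []
    Xc, Yc = grid20_cell_centers()
    for rr in range(GRID20_N):
        for cc in range(GRID20_N):
            sid = f"g_{rr}_{cc}"
            if not keep[rr, cc]:
                reason = ("outside_3mm_circle"
                          if np.hypot(Xc[rr, cc], Yc[rr, cc]) > 3.0
                          else "central_inner_layer_exclusion")
                out.append(SectorSummary("grid20", sid, tmap.layer, float("nan"),
                                         0, excluded=True, reason=reason))
            elif counts[rr, cc] == 0:
                out.append(SectorSummary("grid20", sid, tmap.layer, float("nan"),
                                         0, excluded=True, reason="empty"))
            else:
                out.append(SectorSummary(
                    "grid20", sid, tmap.layer,
                    float(sums[rr, cc] / counts[rr, cc]), int(counts[rr, cc])))
    return out


def grid20_node_mask(tmap: ThicknessMap) -> np.ndarray:
    """Node mask of the union of retained 20 x 20 cells for a layer (used by
    the conservation identity against whole_macula_mean)."""
    _, r, disc, ring, quad, row, col = _check_grid(tmap)
    keep = grid20_retained(tmap.layer)
    return keep[row, col]


def sector_means(tmap: ThicknessMap, scheme: str) -> list[SectorSummary]:
    if scheme == "whole":
        _, r, disc, *_ = _check_grid(tmap)
        use = disc & np.isfinite(tmap.values)
        n = int(use.sum())
        mean = float(tmap.values[use].mean()) if n else float("nan")
        return [SectorSummary("whole", "ALL", tmap.layer, mean, n,
                              excluded=n == 0, reason="" if n else "empty")]
    if scheme == "etdrs":
        return etdrs_means(tmap)
    if scheme == "grid20":
        return grid20_means(tmap)
    raise ValueError(f"unknown scheme {scheme!r}")
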