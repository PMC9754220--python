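"""Fovea-centered thickness maps.

Aligns each eye on its foveal center (arg-min of a smoothed TRT map),
mirrors left eyes into the right-eye frame (+x nasal, +y superior), and
interpolates scattered A-scan samples to regular and radial analysis grids.

The analysis grid covers the 6 x 6 mm scanned field with 300 x 300 nodes
(0.0201 mm spacing).  Interpolation is piecewise-linear on the Delaunay
triangulation of the samples; nodes outside the convex hull are missing
(NaN) — no extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, QhullError

from .config import LAYERS, TRT
from .synthetic import EyeTruth, SegmentedScan, GeneratorConfig

#: Gaussian smoothing width used for fovea localization (mm).
FOVEA_SMOOTH_SIGMA_MM = 0.15
#: Half-width of the central search window for the foveal minimum (mm).
FOVEA_WINDOW_MM = 1.0

N_DIRECTIONS = 24
RADIAL_MAX_MM = 2.0
RADIAL_STEP_MM = 0.1


class LocalizationError(RuntimeError):
    """Fovea localization failed (no usable data in the central window)."""


@dataclass(frozen=True)
class GridSpec:
    """Square uniform grid centered on (0, 0): nodes at
    linspace(-extent, extent, n_nodes) along each axis."""

    extent_mm: float = 3.0
    n_nodes: int = 300

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(-self.extent_mm, self.extent_mm, self.n_nodes)

    @property
    def spacing(self) -> float:
        return 2.0 * self.extent_mm / (self.n_nodes - 1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) with values[j, i] at (x=axis[i], y=axis[j])."""
        return np.meshgrid(self.axis, self.axis)


DEFAULT_GRID = GridSpec()


@dataclass
class ThicknessMap:
    """One layer's thickness on a regular grid; values[j, i] sits at
    (x = xs[i], y = ys[j]).  NaN marks missing nodes."""

    layer: str
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray

    @classmethod
    def on_grid(cls, layer: str, grid: GridSpec, values: np.ndarray) -> "ThicknessMap":
        return cls(layer=layer, xs=grid.axis, ys=grid.axis, values=values)

    @property
    def spacing(self) -> float:
        return float(self.xs[1] - self.xs[0])


# ---------------------------------------------------------------------------
# Interpolation of scattered samples

def triangulate(scan: SegmentedScan) -> Delaunay:
    """Delaunay triangulation of a scan's sample positions (shared by all
    layers of the scan)."""
    pts = np.column_stack([scan.x, scan.y])
    try:
        return Delaunay(pts)
    except QhullError as err:
        raise ValueError(f"degenerate sample geometry: {err}") from err


def interpolate_scan(scan: SegmentedScan, grid: GridSpec = DEFAULT_GRID,
                     layers: tuple[str, ...] | None = None,
                     tri: Delaunay | None = None) -> dict[str, ThicknessMap]:
    """Interpolate all layers of a scan to a regular grid in one pass."""
    if layers is None:
        layers = tuple(scan.layers)
    if tri is None:
        tri = triangulate(scan)
    vals = np.column_stack([scan.layers[l] for l in layers])
    interp = LinearNDInterpolator(tri, vals)
    X, Y = grid.mesh()
    out = interp(X, Y)  # (n, n, len(layers))
    return {l: ThicknessMap.on_grid(l, grid, out[..., k])
            for k, l in enumerate(layers)}


def interpolate_map(x: np.ndarray, y: np.ndarray, values: np.ndarray,
                    grid: GridSpec = DEFAULT_GRID, layer: str = TRT) -> ThicknessMap:
    """Triangulation-based linear interpolation of one scattered field."""
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    pts = np.column_stack([x, y])
    try:
        interp = LinearNDInterpolator(pts, values)
    except QhullError as err:
        raise ValueError(f"degenerate sample geometry: {err}") from err
    X, Y = grid.mesh()
    return ThicknessMap.on_grid(layer, grid, interp(X, Y))


# ---------------------------------------------------------------------------
# Fovea localization

def _smooth_preserving_nan(values: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing with normalized handling of missing nodes."""
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    num = gaussian_filter(filled, sigma_px, truncate=3.0)
    den = gaussian_filter(mask.astype(float), sigma_px, truncate=3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask] = np.nan
    return out


def find_fovea(trt: SegmentedScan | ThicknessMap,
               coarse_spacing_mm: float = 0.05,
               tri: Delaunay | None = None) -> tuple[float, float]:
    """Locate the foveal center as the arg-min of the smoothed TRT map.

    Scattered input is first interpolated to a coarse regular grid (a
    precomputed triangulation of the sample positions may be passed).  The
    smoothed map is searched within the central 2 x 2 mm window; ties are
    broken by distance to the raster center, then lexicographically in
    (x, y).  Returns device-frame coordinates (mm).
    """
    if isinstance(trt, SegmentedScan):
        n = int(round(2 * 3.0 / coarse_spacing_mm)) + 1
        grid = GridSpec(extent_mm=3.0, n_nodes=n)
        if tri is not None:
            interp = LinearNDInterpolator(tri, trt.layers[TRT])
            X, Y = grid.mesh()
            tmap = ThicknessMap.on_grid(TRT, grid, interp(X, Y))
        else:
            tmap = interpolate_map(trt.x, trt.y, trt.layers[TRT], grid)
    else:
        tmap = trt
    sigma_px = FOVEA_SMOOTH_SIGMA_MM / tmap.spacing
    smooth = _smooth_preserving_nan(tmap.values, sigma_px)
    X, Y = np.meshgrid(tmap.xs, tmap.ys)
    window = (np.abs(X) <= FOVEA_WINDOW_MM) & (np.abs(Y) <= FOVEA_WINDOW_MM)
    usable = window & np.isfinite(smooth)
    if not usable.any():
        raise LocalizationError("no usable TRT nodes in the central 2x2 mm window")
    vals = np.where(usable, smooth, np.inf)
    vmin = vals.min()
    jj, ii = np.nonzero(vals <= vmin + 1e-12)
    if jj.size > 1:  # tie-break: nearest to raster center, then lexicographic
        xs, ys = X[jj, ii], Y[jj, ii]
        order = np.lexsort((ys, xs, np.hypot(xs, ys)))
        jj, ii = jj[order[:1]], ii[order[:1]]
    return float(X[jj[0], ii[0]]), float(Y[jj[0], ii[0]])


def normalize_eye(scan: SegmentedScan, center: tuple[float, float]) -> SegmentedScan:
    """Shift sample positions to the foveal center and mirror OS eyes in x,
    yielding the right-eye anatomical frame (+x nasal).  Thickness values
    are untouched."""
    x = scan.x - center[0]
    if scan.eye == "OS":
        x = -x
    return SegmentedScan(subject_id=scan.subject_id, eye=scan.eye,
                         protocol=scan.protocol, x=x, y=scan.y - center[1],
                         layers=dict(scan.layers))


# ---------------------------------------------------------------------------
# Radial resampling

def radial_axes() -> tuple[np.ndarray, np.ndarray]:
    """(angles_deg, radii_mm): 24 directions at 15 deg steps starting at
    0 deg = nasal (+x), counterclockwise; radii 0..2 mm step 0.1."""
    angles = np.arange(N_DIRECTIONS) * (360.0 / N_DIRECTIONS)
    radii = np.round(np.arange(0.0, RADIAL_MAX_MM + RADIAL_STEP_MM / 2, RADIAL_STEP_MM), 10)
    return angles, radii


def radial_resample(tmap: ThicknessMap) -> np.ndarray:
    """Sample a fovea-centered TRT map on the radial analysis grid.

    Returns values of shape (24, 21); the r=0 node is shared across
    directions.  Raises if any requested node has no coverage.
    """
    angles, radii = radial_axes()
    th = np.deg2rad(angles)[:, None]
    Xq = radii[None, :] * np.cos(th)
    Yq = radii[None, :] * np.sin(th)
    interp = RegularGridInterpolator((tmap.ys, tmap.xs), tmap.values,
                                     method="linear", bounds_error=False,
                                     fill_value=np.nan)
    out = interp(np.column_stack([Yq.ravel(), Xq.ravel()])).reshape(N_DIRECTIONS, radii.size)
    out[:, 0] = out[0, 0]  # shared center sample
    if not np.isfinite(out).all():
        bad = np.argwhere(~np.isfinite(out))
        nodes = ", ".join(f"(theta={angles[d]:.0f}deg, r={radii[r]:.1f}mm)"
                          for d, r in bad[:8])
        raise ValueError(f"missing coverage at radial nodes: {nodes}"
                         + (" ..." if len(bad) > 8 else ""))
    return out


# ---------------------------------------------------------------------------
# Grid-mode generation + recentring (exact, for large synthetic cohorts)

GRID_PAD_NODES = 15  # covers fixation offsets up to 15 nodes (~0.3 mm)


@dataclass
class GridScan:
    """One eye generated directly on the (extended) analysis grid, in the
    device frame."""

    subject_id: str
    eye: str
    xs: np.ndarray
    ys: np.ndarray
    layers: dict[str, np.ndarray]


def extended_axis(grid: GridSpec, pad: int = GRID_PAD_NODES) -> np.ndarray:
    h = grid.spacing
    k = np.arange(-(pad), grid.n_nodes + pad)
    return -grid.extent_mm + k * h


def snap_offset(offset: tuple[float, float], grid: GridSpec,
                pad: int = GRID_PAD_NODES) -> tuple[float, float]:
    """Snap a fixation offset to the grid lattice (|shift| <= pad-1 nodes)."""
    h = grid.spacing
    kx = int(np.clip(round(offset[0] / h), -(pad - 1), pad - 1))
    ky = int(np.clip(round(offset[1] / h), -(pad - 1), pad - 1))
    return (kx * h, ky * h)


def evaluate_truth_on_grid(truth: EyeTruth, config: GeneratorConfig,
                           grid: GridSpec = DEFAULT_GRID,
                           template_norms: dict[str, float] | None = None,
                           thickness_shift: float = 0.0,
                           layer_shifts: dict[str, float] | None = None) -> GridScan:
    """Evaluate an eye's surface on the extended analysis grid (device
    frame), with the fixation offset snapped to the lattice so that
    recentring is an exact crop."""
    ax = extended_axis(grid)
    x0, y0 = snap_offset(truth.offset, grid)
    X, Y = np.meshgrid(ax, ax)
    u = (X - x0) if truth.eye == "OD" else -(X - x0)
    v = Y - y0
    if layer_shifts:
        truth = replace(truth, layer_targets={
            k: truth.layer_targets[k] + layer_shifts.get(k, 0.0)
            for k in truth.layer_targets
        })
    fields = truth.evaluate(u, v, config, template_norms=template_norms,
                            thickness_shift=thickness_shift)
    fields = {k: np.maximum(f, 0.0) for k, f in fields.items()}
    fields[TRT] = sum(fields[layer] for layer in LAYERS)
    return GridScan(subject_id=truth.subject.subject_id, eye=truth.eye,
                    xs=ax, ys=ax, layers=fields)


def locate_fovea_grid(scan: GridScan, grid: GridSpec = DEFAULT_GRID) -> tuple[float, float]:
    """Foveal center of a grid-mode scan, snapped to the offset lattice.

    The analysis-grid nodes sit at half-integer offsets from the true
    center (the 300-node axis has no node at 0), so the smoothed-TRT arg-min
    node is refined by a one-node parabolic fit per axis and then snapped to
    the nearest lattice multiple of the grid spacing — which is exactly the
    set of fixation offsets grid-mode generation can produce.
    """
    tmap = ThicknessMap(TRT, scan.xs, scan.ys, scan.layers[TRT])
    sigma_px = FOVEA_SMOOTH_SIGMA_MM / tmap.spacing
    smooth = _smooth_preserving_nan(tmap.values, sigma_px)
    X, Y = np.meshgrid(tmap.xs, tmap.ys)
    window = (np.abs(X) <= FOVEA_WINDOW_MM) & (np.abs(Y) <= FOVEA_WINDOW_MM)
    usable = window & np.isfinite(smooth)
    if not usable.any():
        raise LocalizationError("no usable TRT nodes in the central 2x2 mm window")
    vals = np.where(usable, smooth, np.inf)
    j, i = np.unravel_index(np.argmin(vals), vals.shape)
    x = tmap.xs[i] + _parabolic_shift(smooth[j, max(i - 1, 0):i + 2]) * tmap.spacing
    y = tmap.ys[j] + _parabolic_shift(smooth[max(j - 1, 0):j + 2, i]) * tmap.spacing
    h = grid.spacing
    return (round(x / h) * h, round(y / h) * h)


def _parabolic_shift(triple: np.ndarray) -> float:
    """Sub-node offset of a 1-d minimum from a 3-point parabola, in nodes."""
    if triple.size != 3 or not np.isfinite(triple).all():
        return 0.0
    a, b, c = triple
    denom = a - 2 * b + c
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def recenter_grid_scan(scan: GridScan, center: tuple[float, float],
                       grid: GridSpec = DEFAULT_GRID) -> dict[str, ThicknessMap]:
    """Crop an extended-grid scan to the fovea-centered analysis window and
    mirror OS eyes.  The center must be a lattice multiple of the grid
    spacing (grid-mode fixation offsets are snapped to that lattice)."""
    h = grid.spacing
    i0f = (center[0] - scan.xs[0] - grid.extent_mm) / h
    j0f = (center[1] - scan.ys[0] - grid.extent_mm) / h
    i0, j0 = int(round(i0f)), int(round(j0f))
    if abs(i0f - i0) > 1e-6 or abs(j0f - j0) > 1e-6:
        raise ValueError("center does not lie on the grid-scan offset lattice")
    i1, j1 = i0 + grid.n_nodes, j0 + grid.n_nodes
    if j0 < 0 or i0 < 0 or j1 > scan.ys.size or i1 > scan.xs.size:
        raise ValueError("fovea-centered window exceeds the scanned field")
    maps = {}
    for layer, vals in scan.layers.items():
        window = vals[j0:j1, i0:i1]
        if scan.eye == "OS":
            window = window[:, ::-1]
        maps[layer] = ThicknessMap.on_grid(layer, grid, window.copy())
    return maps


def grid_template_norms(config: GeneratorConfig,
                        grid: GridSpec = DEFAULT_GRID) -> dict[str, float]:
    """Discrete disc-node means of the raw layer templates on the analysis
    grid; used by grid mode so whole-macula means recover the layer targets
    exactly in the noiseless limit."""
    from .synthetic import _TEMPLATE_SHAPES

    X, Y = grid.mesh()
    r = np.hypot(X, Y)
    disc = r <= grid.extent_mm
    # the centered window samples the templates at the same node offsets for
    # every eye, so one set of means is exact for all
    return {layer: float(shape(r[disc]).mean())
            for layer, shape in _TEMPLATE_SHAPES.items()}
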