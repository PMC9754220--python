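"""Foveal pit morphometry from radial TRT profiles.

For each of 24 angular directions the TRT profile (21 radii, 0-2 mm, 0.1 mm
steps) is LOESS-smoothed (span 50%, local quadratic, tricube weights); the
rim is the arg-max of the smoothed profile over r > 0 (ties broken toward
the center).  Derived per-direction metrics:

* rim height — smoothed TRT at the rim (um);
* rim radius — radial distance of the rim from the center (mm);
* mean slope — mean of the per-step inclination angles
  atan(dT/dr) of the *unsmoothed* profile between center and rim, with dT
  converted from um to mm (degrees).

Central foveal thickness (CFT) is the raw TRT at r = 0 and does not vary
with direction.  Whole-macula values are unweighted means of the 24
directional metrics (CFT passed through).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .maps import radial_axes

LOESS_SPAN = 0.5
RIM_AT_BOUNDARY = "rim_at_boundary"


@dataclass
class RadialProfile:
    """TRT on the radial analysis grid; values shape (n_directions, n_radii)
    with a shared r = 0 sample."""

    angles_deg: np.ndarray
    radii_mm: np.ndarray
    values: np.ndarray
    smoothed: np.ndarray | None = None

    @classmethod
    def from_values(cls, values: np.ndarray) -> "RadialProfile":
        angles, radii = radial_axes()
        return cls(angles_deg=angles, radii_mm=radii, values=np.asarray(values, float))


@dataclass(frozen=True)
class FovealPitResult:
    """Whole-macula pit descriptors (directional means except CFT)."""

    cft_um: float
    rim_height_um: float
    rim_radius_mm: float
    mean_slope_deg: float
    flags: tuple[str, ...] = ()


@dataclass
class DirectionalPit:
    """Per-direction pit metrics for one eye."""

    angles_deg: np.ndarray
    cft_um: float
    rim_height_um: np.ndarray
    rim_radius_mm: np.ndarray
    mean_slope_deg: np.ndarray
    flags: list[tuple[str, ...]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LOESS

@lru_cache(maxsize=32)
def _loess_matrix(radii_key: tuple, span: float, degree: int) -> np.ndarray:
    """Linear smoother matrix S for LOESS at fixed design points: fitted
    values are S @ y.  Local weighted quadratic regression at each point
    using the nearest ceil(span*n) neighbours with tricube weights on the
    distance scaled by the window radius."""
    r = np.asarray(radii_key, dtype=float)
    n = r.size
    q = max(int(math.ceil(span * n)), degree + 1)
    q = min(q, n)
    S = np.zeros((n, n))
    for i in range(n):
        d = np.abs(r - r[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            raise ValueError("duplicated radii make the local fit singular")
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        X = np.vander(r[idx] - r[i], degree + 1, increasing=True)
        XtW = X.T * w
        A = XtW @ X
        try:
            row = np.linalg.solve(A, XtW)[0]
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular local design at r={r[i]}: {err}") from err
        S[i, idx] = row
    return S


def loess_smooth(values: np.ndarray, radii: np.ndarray,
                 span: float = LOESS_SPAN, degree: int = 2) -> np.ndarray:
    """LOESS-smooth one or many profiles sampled at ``radii``.

    ``values`` may be (n,) or (n_profiles, n); the fitted value at each of
    the original radii is returned.  Requires at least 5 points.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 5:
        raise ValueError("need at least 5 points per direction")
    S = _loess_matrix(tuple(radii), float(span), int(degree))
    return np.asarray(values, dtype=float) @ S.T


# ---------------------------------------------------------------------------
# Pit parameters

def pit_params(profile: RadialProfile, span: float = LOESS_SPAN) -> DirectionalPit:
    """Per-direction pit metrics from raw + smoothed radial profiles."""
    raw = profile.values
    if profile.smoothed is None:
        profile.smoothed = loess_smooth(raw, profile.radii_mm, span=span)
    sm = profile.smoothed
    radii = profile.radii_mm
    n_dir, n_r = raw.shape
    cft = float(raw[0, 0])
    rim_idx = 1 + np.argmax(sm[:, 1:], axis=1)  # first max <=> smallest radius
    rim_height = sm[np.arange(n_dir), rim_idx]
    rim_radius = radii[rim_idx]
    dr = np.diff(radii)
    step_angles = np.degrees(np.arctan(np.diff(raw, axis=1) / 1000.0 / dr))
    mean_slope = np.empty(n_dir)
    flags: list[tuple[str, ...]] = []
    for d in range(n_dir):
        mean_slope[d] = step_angles[d, :rim_idx[d]].mean()
        flags.append((RIM_AT_BOUNDARY,) if rim_idx[d] == n_r - 1 else ())
    return DirectionalPit(angles_deg=profile.angles_deg, cft_um=cft,
                          rim_height_um=rim_height, rim_radius_mm=rim_radius,
                          mean_slope_deg=mean_slope, flags=flags)


def aggregate_pit(directional: DirectionalPit) -> FovealPitResult:
    """Whole-macula aggregate: unweighted directional means; CFT passed
    through; any directional flag propagates."""
    flags = tuple(sorted({f for fl in directional.flags for f in fl}))
    return FovealPitResult(
        cft_um=directional.cft_um,
        rim_height_um=float(directional.rim_height_um.mean()),
        rim_radius_mm=float(directional.rim_radius_mm.mean()),
        mean_slope_deg=float(directional.mean_slope_deg.mean()),
        flags=flags,
    )


def analyze_pit(trt_radial_values: np.ndarray,
                span: float = LOESS_SPAN) -> tuple[DirectionalPit, FovealPitResult]:
    """Convenience: directional + aggregate pit metrics from radial TRT."""
    profile = RadialProfile.from_values(trt_radial_values)
    per_dir = pit_params(profile, span=span)
    return per_dir, aggregate_pit(per_dir)
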