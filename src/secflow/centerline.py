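"""Vessel centerline containers and differential geometry.

A centerline is an ordered 3-D polyline parameterized by its arc length
(the *abscissa* ``s``), optionally carrying a per-point lumen radius
(maximum inscribed sphere radius, MISR).  All lengths are in millimetres.

The module provides arc-length resampling, iterative midpoint smoothing,
and discrete Frenet-Serret frames: the tangent/normal/binormal triad
together with curvature ``kappa`` [1/mm] and torsion ``tau`` [1/mm],
computed by second-order finite differences on a uniformly resampled
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Centerline",
    "FrenetFrameSet",
    "resample",
    "smooth",
    "frenet",
    "misr_profile",
    "DEFAULT_SPACING_MM",
    "DEFAULT_SMOOTH_FACTOR",
    "DEFAULT_SMOOTH_ITERATIONS",
]

# Default processing parameters for clinical-resolution centerlines.
DEFAULT_SPACING_MM = 0.15
DEFAULT_SMOOTH_FACTOR = 1.0
DEFAULT_SMOOTH_ITERATIONS = 75

#: |C' x C''| below this [1/mm] means curvature is numerically zero and
#: the normal/binormal/torsion are undefined there.
DEGENERATE_CROSS_TOL = 1e-8


def _as_points(points: Any) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
    if pts.shape[0] < 3:
        raise ValueError("a centerline needs at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("centerline points must be finite")
    return pts


def _chord_abscissa(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("centerline has coincident consecutive points")
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Centerline:
    """Ordered 3-D polyline with cumulative arc length and optional MISR.

    The abscissa is always the cumulative chord length of ``points``,
    starting at 0 at the proximal (inlet) end.
    """

    points: np.ndarray
    radius: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)
    abscissa: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        self.abscissa = _chord_abscissa(self.points)
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
            if self.radius.shape != (len(self.points),):
                raise ValueError("radius must be one value per point")
            if np.any(self.radius <= 0):
                raise ValueError("radius values must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total polyline length [mm]."""
        return float(self.abscissa[-1])

    @property
    def spacing(self) -> float:
        """Mean point spacing [mm]."""
        return self.length / (len(self) - 1)

    def with_radius(self, radius: np.ndarray) -> "Centerline":
        return replace(self, points=self.points, radius=np.asarray(radius, float))


@dataclass
class FrenetFrameSet:
    """Per-point Frenet frames along a uniformly sampled centerline.

    ``valid`` is False where the frame is undefined: either the curve is
    locally straight (|C' x C''| below tolerance) or the point is too
    close to an endpoint for the nested finite-difference stencils to
    hold their interior accuracy (outermost four points per end — the
    third derivative inherits one-sided edge errors three points deep).
    """

    abscissa: np.ndarray
    t: np.ndarray  # tangent unit vectors (n, 3)
    n: np.ndarray  # normal unit vectors (n, 3); NaN where invalid
    b: np.ndarray  # binormal unit vectors (n, 3); NaN where invalid
    kappa: np.ndarray  # curvature [1/mm], >= 0
    tau: np.ndarray  # torsion [1/mm]; NaN where invalid
    valid: np.ndarray  # bool mask

    def __len__(self) -> int:
        return len(self.abscissa)


def resample(c: Centerline, spacing: float) -> Centerline:
    """Resample a centerline at uniform arc-length intervals.

    Points are placed every ``spacing`` mm along the input polyline by
    linear interpolation; the first and last input points are preserved,
    so the final interval may be shorter (flagged in metadata as
    ``last_interval_short``).  The radius profile, if present, is
    linearly interpolated.
    """
    total = c.length
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    if spacing >= total:
        raise ValueError(f"spacing {spacing} mm >= total length {total:.6g} mm")
    n_full = int(np.floor(total / spacing + 1e-9))
    s_new = spacing * np.arange(n_full + 1)
    short = total - s_new[-1] > 1e-9 * max(1.0, total)
    if short:
        s_new = np.append(s_new, total)
    else:
        s_new[-1] = total
    pts = np.column_stack([np.interp(s_new, c.abscissa, c.points[:, k]) for k in range(3)])
    pts[0] = c.points[0]
    pts[-1] = c.points[-1]
    rad = None
    if c.radius is not None:
        rad = np.interp(s_new, c.abscissa, c.radius)
    meta = dict(c.metadata)
    meta["last_interval_short"] = bool(short)
    meta["resample_spacing_mm"] = float(spacing)
    return Centerline(pts, radius=rad, metadata=meta)


def smooth(c: Centerline, factor: float = DEFAULT_SMOOTH_FACTOR,
           iterations: int = DEFAULT_SMOOTH_ITERATIONS) -> Centerline:
    """Iterative midpoint relaxation with fixed endpoints.

    Each pass moves every interior point toward the midpoint of its
    neighbours: ``p_i <- p_i + factor * ((p_{i-1}+p_{i+1})/2 - p_i)``.
    The result is re-parameterized by arc length (the abscissa is
    recomputed from the moved points).
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = c.points.copy()
    for _ in range(int(iterations)):
        pts[1:-1] += factor * (0.5 * (pts[:-2] + pts[2:]) - pts[1:-1])
    return Centerline(pts, radius=None if c.radius is None else c.radius.copy(),
                      metadata=dict(c.metadata))


def _check_uniform(c: Centerline) -> float:
    """Reject grossly unparameterized input; the derivatives themselves
    use the abscissa and tolerate mild chord-length variation (noisy
    polylines resampled by arc length shortcut their own zigzag)."""
    seg = np.diff(c.abscissa)
    # allow a shorter final interval (resample preserves the endpoint)
    core = seg[:-1] if len(seg) > 1 else seg
    h = float(np.mean(core))
    if np.max(np.abs(core - h)) > 0.5 * h:
        raise ValueError("centerline must be (approximately) uniformly resampled "
                         "before frenet()")
    return h


def frenet(c: Centerline) -> FrenetFrameSet:
    """Discrete Frenet-Serret frames, curvature and torsion.

    Derivatives C', C'', C''' are taken by nested second-order finite
    differences (central in the interior, one-sided at the ends); then

        kappa = |C' x C''| / |C'|^3
        tau   = (C' x C'') . C''' / |C' x C''|^2
        t = C'/|C'|,  n = unit component of C'' orthogonal to t,  b = t x n

    Points where |C' x C''| falls below tolerance (locally straight
    curve) and the outermost four points at each end (incomplete
    stencil support for the nested third derivative) are masked
    invalid; their n, b and tau are NaN.
    """
    if len(c) < 5:
        raise ValueError("frenet() needs at least 5 points")
    _check_uniform(c)
    s = c.abscissa  # abscissa-aware gradients absorb the shorter last interval
    d1 = np.gradient(c.points, s, axis=0, edge_order=2)
    d2 = np.gradient(d1, s, axis=0, edge_order=2)
    d3 = np.gradient(d2, s, axis=0, edge_order=2)

    cr = np.cross(d1, d2)
    crn = np.linalg.norm(cr, axis=1)
    speed = np.linalg.norm(d1, axis=1)
    kappa = crn / speed**3

    valid = crn >= DEGENERATE_CROSS_TOL
    valid[:4] = False
    valid[-4:] = False

    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.einsum("ij,ij->i", cr, d3) / crn**2
    tau[~valid] = np.nan

    t = d1 / speed[:, None]
    # normal from the component of C'' orthogonal to the tangent: this
    # enforces t.n = 0 exactly instead of relying on |C'| being constant
    n_raw = d2 - np.einsum("ij,ij->i", d2, t)[:, None] * t
    n_norm = np.linalg.norm(n_raw, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = n_raw / n_norm[:, None]
    n[~valid] = np.nan
    b = np.cross(t, n)

    return FrenetFrameSet(abscissa=c.abscissa.copy(), t=t, n=n, b=b,
                          kappa=kappa, tau=tau, valid=valid)


def misr_profile(c: Centerline, lumen: np.ndarray) -> np.ndarray:
    """Per-point lumen radius (MISR analogue) along the centerline.

    ``lumen`` is either a surface point set of shape (m, 3) — the radius
    at centerline point i is then its minimum distance to the surface —
    or an analytic per-point radius array of shape (n,), returned as is.
    """
    lum = np.asarray(lumen, dtype=float)
    if lum.size == 0:
        raise ValueError("lumen input is empty")
    if lum.ndim == 1:
        if lum.shape[0] != len(c):
            raise ValueError("analytic radius must have one value per centerline point")
        return lum.copy()
    if lum.ndim != 2 or lum.shape[1] != 3:
        raise ValueError("lumen must be (m, 3) surface points or (n,) radii")
    dist, _ = cKDTree(lum).query(c.points)
    return np.asarray(dist, dtype=float)
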