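"""Cross-sectional slicing and velocity decomposition.

Perpendicular slices are planes through centerline points spanned by
the local Frenet normal/binormal; each slice carries a polar sample
grid scaled per ray by the local wall distance.  Velocities are
interpolated onto the samples from a scattered point cloud (the way a
CFD export would be consumed), then decomposed into

    v_ax  = (v . t) t          axial component
    v_sec = v - v_ax           secondary (in-plane) component
    r_rad = (r - p)/|r - p|    radial unit vector from the slice center
    v_rad = (v_sec . r_rad) r_rad
    v_cir = v_sec - v_rad

which is an orthogonal split: |v|^2 = |v_ax|^2 + |v_rad|^2 + |v_cir|^2.

Near-wall region-of-interest averaging follows the parabolic-profile
convention: the band where a unit Poiseuille profile falls below half
its peak, i.e. normalized radius rho >= sqrt(0.5).  The aneurysmal
(A-side) sector is a configurable wedge (default 150 degrees) centered
on the aneurysm's in-plane direction; the opposing (O-side) sector has
the same width, 180 degrees away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .centerline import Centerline, FrenetFrameSet

__all__ = [
    "CrossSection",
    "RoiSummary",
    "OrientationClass",
    "make_slices",
    "sample_velocity",
    "decompose",
    "straighten",
    "classify_orientation",
    "aneurysm_theta",
    "near_wall_threshold",
    "roi_average",
]

#: default ROI parameters: sector width [deg] and the fraction of the
#: parabolic peak that bounds the near-wall band
DEFAULT_SECTOR_DEG = 150.0
DEFAULT_WALL_FRACTION = 0.5

#: orientation angle bands [deg]: "out" within OUT_MAX of the normal,
#: "top" within 90 +/- TOP_HALFWIDTH, otherwise "tilted"
OUT_MAX_DEG = 30.0
TOP_HALFWIDTH_DEG = 30.0

_CENTER_EPS = 1e-9  # samples closer than this to the slice center [mm]


@dataclass
class CrossSection:
    """One perpendicular slice with its polar sample grid.

    ``rho`` is the normalized radius (1 at the wall), ``theta`` the
    polar angle measured from the Frenet normal toward the binormal.
    ``mask`` marks samples with valid interpolated velocities;
    ``polar_ok`` additionally excludes samples at the slice center
    where the radial direction is undefined.
    """

    index: int
    abscissa: float
    center: np.ndarray  # (3,) [mm]
    t: np.ndarray
    n: np.ndarray
    b: np.ndarray
    rho: np.ndarray  # (m,)
    theta: np.ndarray  # (m,)
    wall: np.ndarray  # per-sample wall distance [mm]
    points: np.ndarray  # (m, 3) [mm]
    v: np.ndarray | None = None  # (m, 3) [m/s]
    v_ax: np.ndarray | None = None
    v_rad: np.ndarray | None = None
    v_cir: np.ndarray | None = None
    mask: np.ndarray | None = None
    polar_ok: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.polar_ok is None:
            r = np.linalg.norm(self.points - self.center, axis=1)
            self.polar_ok = r >= _CENTER_EPS


@dataclass(frozen=True)
class RoiSummary:
    """Near-wall sector means of sample-wise velocity magnitudes."""

    side: str  # "A-side" | "O-side"
    mean_v: float
    mean_v_ax: float
    mean_v_cir: float
    mean_v_rad: float
    count: int


@dataclass(frozen=True)
class OrientationClass:
    """Aneurysm orientation relative to the Frenet normal."""

    label: str  # "out" | "top" | "tilted"
    angle_deg: float  # mean in-plane angle to the normal, [0, 180]


# --------------------------------------------------------------------------
# slicing
# --------------------------------------------------------------------------

def _polar_grid(n_rho: int, n_theta: int) -> tuple[np.ndarray, np.ndarray]:
    rho = np.arange(1, n_rho + 1) / n_rho
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    rg, tg = np.meshgrid(rho, theta, indexing="ij")
    return rg.ravel(), tg.ravel()


def make_slices(
    c: Centerline,
    frames: FrenetFrameSet,
    n_rho: int = 16,
    n_theta: int = 64,
    stride: int = 1,
    wall_distance: np.ndarray | None = None,
) -> list[CrossSection]:
    """Build one perpendicular slice per valid centerline point.

    The wall distance per ray defaults to the centerline's radius
    profile (circular lumen — exact for the synthetic tubes); pass
    ``wall_distance`` with shape (n_points,) or (n_points, n_theta) to
    supply per-ray distances for non-circular lumens.
    """
    if len(frames) != len(c):
        raise ValueError("frames and centerline lengths must match")
    if wall_distance is None:
        if c.radius is None:
            raise ValueError("no radius profile and no wall_distance given")
        wall_distance = c.radius
    wall_distance = np.asarray(wall_distance, float)

    rho, theta = _polar_grid(n_rho, n_theta)
    ct, st = np.cos(theta), np.sin(theta)
    slices: list[CrossSection] = []
    for i in range(0, len(c), stride):
        if not frames.valid[i]:
            continue
        wd = wall_distance[i]
        if np.ndim(wd) == 0:
            wall = np.full(rho.shape, float(wd))
        else:
            # per-ray distances come ordered by theta; the grid raveling
            # is rho-major, so tile across the rho shells
            wall = np.tile(np.asarray(wd, float), n_rho)
        e_r = np.outer(ct, frames.n[i]) + np.outer(st, frames.b[i])
        pts = c.points[i] + (rho * wall)[:, None] * e_r
        slices.append(CrossSection(
            index=i, abscissa=float(c.abscissa[i]), center=c.points[i].copy(),
            t=frames.t[i].copy(), n=frames.n[i].copy(), b=frames.b[i].copy(),
            rho=rho.copy(), theta=theta.copy(), wall=wall, points=pts))
    return slices


def wall_from_field(
    center: np.ndarray,
    n_vec: np.ndarray,
    b_vec: np.ndarray,
    theta: np.ndarray,
    tree: cKDTree,
    support_radius: float,
    r_max: float,
    step: float,
) -> np.ndarray:
    """Per-ray wall distance by marching outward through a point cloud.

    Along each ray the wall is placed where the nearest field point
    moves farther than ``support_radius`` (the local cloud support) —
    the point-cloud analogue of leaving the lumen.
    """
    out = np.empty(len(theta))
    dirs = np.outer(np.cos(theta), n_vec) + np.outer(np.sin(theta), b_vec)
    radii = np.arange(step, r_max + step, step)
    for j, d in enumerate(dirs):
        probes = center + radii[:, None] * d
        dist, _ = tree.query(probes)
        outside = np.nonzero(dist > support_radius)[0]
        out[j] = radii[outside[0]] if outside.size else r_max
    return out


# --------------------------------------------------------------------------
# interpolation
# --------------------------------------------------------------------------

def _estimate_spacing(tree: cKDTree, points: np.ndarray, rng_cap: int = 2000) -> float:
    sub = points[:: max(1, len(points) // rng_cap)]
    d, _ = tree.query(sub, k=2)
    return float(np.mean(d[:, 1]))


def sample_velocity(
    slices: CrossSection | Sequence[CrossSection],
    field_points: np.ndarray,
    field_velocities: np.ndarray,
    k: int = 8,
    power: float = 2.0,
    cutoff: float | None = None,
) -> list[CrossSection]:
    """Inverse-distance-weighted interpolation onto slice samples.

    For each sample the velocity is the 1/d^power weighted mean of its
    ``k`` nearest field points, short-circuited to the exact field value
    when a sample coincides with a field point.  Samples whose nearest
    field point is farther than ``cutoff`` (default 1.5x the mean field
    spacing) are masked as outside the lumen.

    Regular field clouds produce exact distance ties at the k-th
    neighbor; the neighbor set is therefore extended to every point
    within the k-th distance (small relative tolerance), which keeps the
    interpolant invariant under rigid motions of cloud and samples.
    """
    field_points = np.asarray(field_points, float)
    field_velocities = np.asarray(field_velocities, float)
    if field_points.size == 0:
        raise ValueError("velocity field is empty")
    single = isinstance(slices, CrossSection)
    slc = [slices] if single else list(slices)
    if not slc:
        return []

    tree = cKDTree(field_points)
    if cutoff is None:
        cutoff = 1.5 * _estimate_spacing(tree, field_points)

    all_pts = np.concatenate([s.points for s in slc])
    kk = min(k, len(field_points))
    # a few spare neighbors to absorb exact ties at the k-th distance
    kq = min(kk + 4, len(field_points))
    dist, idx = tree.query(all_pts, k=kq)
    dist = np.atleast_2d(dist.reshape(len(all_pts), kq))
    idx = idx.reshape(len(all_pts), kq)

    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    w[dist > dist[:, kk - 1, None] * (1.0 + 1e-9)] = 0.0
    w[exact] = 0.0
    w[exact, 0] = 1.0
    v = np.einsum("ij,ijk->ik", w, field_velocities[idx]) / w.sum(axis=1)[:, None]
    mask = dist[:, 0] <= cutoff

    pos = 0
    for s in slc:
        m = len(s.points)
        s.v = v[pos:pos + m]
        s.mask = mask[pos:pos + m]
        pos += m
    return slc


# --------------------------------------------------------------------------
# decomposition and straightening
# --------------------------------------------------------------------------

def decompose(slices: CrossSection | Sequence[CrossSection]) -> list[CrossSection]:
    """Split sampled velocities into axial, radial and circumferential parts.

    Samples at the slice center (|r - p| below tolerance) have no radial
    direction; they are excluded from radial/circumferential statistics
    via ``polar_ok`` but keep their axial component.
    """
    single = isinstance(slices, CrossSection)
    slc = [slices] if single else list(slices)
    for s in slc:
        if s.v is None:
            raise ValueError("sample velocities before decomposing")
        v_dot_t = s.v @ s.t
        s.v_ax = v_dot_t[:, None] * s.t
        v_sec = s.v - s.v_ax
        rel = s.points - s.center
        rn = np.linalg.norm(rel, axis=1)
        ok = rn >= _CENTER_EPS
        r_rad = np.zeros_like(rel)
        r_rad[ok] = rel[ok] / rn[ok, None]
        s.v_rad = np.einsum("ij,ij->i", v_sec, r_rad)[:, None] * r_rad
        s.v_cir = v_sec - s.v_rad
        s.v_cir[~ok] = 0.0
        s.polar_ok = ok
    return slc


def straighten(slice_: CrossSection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid map sending the slice into the global frame: n->x, b->y, t->z.

    Returns ``(coords, R, p)`` where ``coords = (points - p) @ R.T`` and
    ``R`` has rows (n, b, t); det(R) = +1 since the frame is
    right-handed, so the map is a proper isometry.
    """
    if not np.all(np.isfinite(slice_.n)):
        raise ValueError("degenerate frame: slice cannot be straightened")
    R = np.vstack([slice_.n, slice_.b, slice_.t])
    coords = (slice_.points - slice_.center) @ R.T
    return coords, R, slice_.center.copy()


# --------------------------------------------------------------------------
# aneurysm orientation and ROI averaging
# --------------------------------------------------------------------------

def _in_plane(direction: np.ndarray, s: CrossSection) -> np.ndarray:
    d = np.asarray(direction, float)
    return d - (d @ s.t) * s.t


def classify_orientation(
    direction: np.ndarray,
    neck_slices: Sequence[CrossSection],
    out_max_deg: float = OUT_MAX_DEG,
    top_halfwidth_deg: float = TOP_HALFWIDTH_DEG,
) -> OrientationClass:
    """Classify the aneurysm direction against the Frenet normal.

    The direction is projected into each neck slice plane; the angle to
    the normal (0..180 deg) is averaged over neck slices.  "out" means
    the aneurysm leans along the normal (angle <= ``out_max_deg``),
    "top" along the binormal (within ``top_halfwidth_deg`` of 90),
    anything else is "tilted".
    """
    if len(neck_slices) == 0:
        raise ValueError("no neck slices to classify against")
    angles = []
    for s in neck_slices:
        dip = _in_plane(direction, s)
        nrm = np.linalg.norm(dip)
        if nrm < 1e-12:
            continue
        cosang = np.clip((dip / nrm) @ s.n, -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    if not angles:
        raise ValueError("aneurysm direction parallel to the tangent on every neck slice")
    ang = float(np.mean(angles))
    if ang <= out_max_deg:
        label = "out"
    elif abs(ang - 90.0) <= top_halfwidth_deg:
        label = "top"
    else:
        label = "tilted"
    return OrientationClass(label=label, angle_deg=ang)


def aneurysm_theta(direction: np.ndarray, s: CrossSection) -> float:
    """Polar angle [rad] of the aneurysm direction in the slice plane."""
    dip = _in_plane(direction, s)
    if np.linalg.norm(dip) < 1e-12:
        raise ValueError("aneurysm direction has no in-plane component")
    return float(np.arctan2(dip @ s.b, dip @ s.n))


def near_wall_threshold(wall_fraction: float = DEFAULT_WALL_FRACTION) -> float:
    """Normalized radius where a unit parabolic profile 1 - rho^2 drops
    to ``wall_fraction`` of its peak: the root of 1 - rho^2 = wall_fraction."""
    if not 0 < wall_fraction < 1:
        raise ValueError("wall_fraction must be in (0, 1)")
    return float(np.sqrt(1.0 - wall_fraction))


def _angdist(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.abs((theta - center + np.pi) % (2 * np.pi) - np.pi)
    return d


def roi_average(
    s: CrossSection,
    theta_center: float,
    sector_deg: float = DEFAULT_SECTOR_DEG,
    wall_fraction: float = DEFAULT_WALL_FRACTION,
) -> tuple[RoiSummary, RoiSummary]:
    """Near-wall sector means on the aneurysmal and opposing sides.

    The near-wall band keeps samples with normalized radius
    rho >= sqrt(1 - wall_fraction) — where a unit parabolic profile
    1 - rho^2 drops below ``wall_fraction`` of its peak.  The A-side
    sector of width ``sector_deg`` is centered on ``theta_center``
    (the aneurysm's in-plane angle); the O-side sector has the same
    width and the opposite center.  Means are of sample-wise magnitudes.
    """
    if not 0 < sector_deg <= 180:
        raise ValueError("sector_deg must be in (0, 180]")
    if not 0 < wall_fraction < 1:
        raise ValueError("wall_fraction must be in (0, 1)")
    if s.v_ax is None:
        raise ValueError("decompose the slice before ROI averaging")
    rho_star = near_wall_threshold(wall_fraction)
    half = np.radians(sector_deg) / 2.0
    band = (s.rho >= rho_star - 1e-12) & s.mask & s.polar_ok
    sel_a = band & (_angdist(s.theta, theta_center) <= half)
    # strict inequality on the O-side keeps the two sectors disjoint
    # when sector_deg = 180
    sel_o = band & (_angdist(s.theta, theta_center + np.pi) < half)

    def summary(sel: np.ndarray, side: str) -> RoiSummary:
        cnt = int(np.count_nonzero(sel))
        if cnt == 0:
            return RoiSummary(side, 0.0, 0.0, 0.0, 0.0, 0)
        return RoiSummary(
            side,
            float(np.mean(np.linalg.norm(s.v[sel], axis=1))),
            float(np.mean(np.linalg.norm(s.v_ax[sel], axis=1))),
            float(np.mean(np.linalg.norm(s.v_cir[sel], axis=1))),
            float(np.mean(np.linalg.norm(s.v_rad[sel], axis=1))),
            cnt,
        )

    return summary(sel_a, "A-side"), summary(sel_o, "O-side")
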