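"""Synthetic vessels and analytic flow fields.

The patient data behind this kind of analysis (segmented internal
carotid arteries and CFD velocity fields) are not something one can
regenerate at a desk, so this module builds parametric stand-ins with
the statistical structure the analysis pipeline assumes:

* helix/circle centerlines with closed-form curvature and torsion,
* multi-bend centerlines whose curvature peaks are flanked by torsion
  peaks (the geometry the bend landmarking step expects), generated by
  prescribing smooth kappa(s) and tau(s) profiles and integrating the
  Frenet-Serret equations,
* an analytic velocity field per vessel: a parabolic axial profile plus
  a Dean-like counter-rotating vortex pair whose amplitude scales with
  the local curvature, exported as a scattered point cloud,
* a cohort generator producing many such cases with a designated
  "aneurysmal" bend whose curvature is shifted upward by a configurable
  effect size.

Units: lengths mm, velocities m/s, flow rates ml/s.  The single place
where these meet is :func:`mean_axial_velocity`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .centerline import Centerline

__all__ = [
    "HelixSpec",
    "BendSpec",
    "FlowSpec",
    "SyntheticCase",
    "make_helix_centerline",
    "make_multibend_centerline",
    "inflow_from_area",
    "murray_split",
    "make_flow_field",
    "make_population",
    "mean_axial_velocity",
    "secondary_amplitude",
]

#: coefficient and exponent of the cycle-averaged ICA inflow scaling law
#: Q [ml/s] = 48.21 * A[cm^2]^1.84 / T[s]
INFLOW_COEFF = 48.21
INFLOW_AREA_EXP = 1.84

#: baseline curvature [1/mm] of multibend curves outside the bend bumps;
#: kept positive so torsion stays defined everywhere along the curve
BASELINE_KAPPA = 0.02


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Circular helix (a cos t, a sin t, b t): kappa = a/(a^2+b^2), tau = b/(a^2+b^2)."""

    a: float  # helix radius [mm]
    b: float  # pitch parameter [mm]
    arc_length: float  # total arc length [mm]
    spacing: float  # point spacing along the arc [mm]

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("helix radius a must be positive")
        if self.b < 0:
            raise ValueError("pitch parameter b must be >= 0")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.arc_length < 2 * self.spacing:
            raise ValueError("arc_length must be at least two spacings")


@dataclass(frozen=True)
class BendSpec:
    """One arterial bend: a curvature bump of given peak and extent."""

    peak_curvature: float  # [1/mm]
    bend_arc_length: float  # [mm]
    twist_angle: float = 0.0  # out-of-plane rotation vs previous bend [degrees]

    def __post_init__(self) -> None:
        if self.peak_curvature < 0:
            raise ValueError("peak_curvature must be >= 0")
        if not self.bend_arc_length > 0:
            raise ValueError("bend_arc_length must be positive")


@dataclass(frozen=True)
class FlowSpec:
    """Flow parameterization for the analytic field.

    The secondary (vortex-pair) amplitude at a cross-section is
    ``coupling_c * kappa_local * R_local * U_mean_local`` — the
    dimensionless product kappa*R is the curvature ratio that drives
    Dean-type secondary flow in curved pipes.
    """

    Q: float  # cycle-averaged flow rate [ml/s]
    coupling_c: float = 1.0  # dimensionless secondary-flow coupling
    noise_sigma: float = 0.0  # additive velocity noise std [m/s]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise ValueError("Q must be positive")
        if self.coupling_c < 0:
            raise ValueError("coupling_c must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticCase:
    """One synthetic patient: geometry, flow field, aneurysm annotation."""

    case_id: str
    centerline: Centerline  # carries the radius profile
    field_points: np.ndarray | None  # (m, 3) [mm]
    field_velocities: np.ndarray | None  # (m, 3) [m/s]
    aneurysm_bend_index: int
    aneurysm_direction: np.ndarray  # unit vector
    neck_start_abscissa: float
    neck_end_abscissa: float
    orientation_class: str  # "out" | "top" | "tilted"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bounds = self.ground_truth.get("bend_bounds")
        if bounds is not None:
            if not 0 <= self.aneurysm_bend_index < len(bounds):
                raise ValueError("aneurysm_bend_index out of range")
            flat = np.asarray(bounds).ravel()
            starts = np.asarray([b[0] for b in bounds])
            if not np.all(np.diff(starts) > 0):
                raise ValueError("bend boundaries must increase along the abscissa")
        d = np.asarray(self.aneurysm_direction, float)
        self.aneurysm_direction = d / np.linalg.norm(d)


# --------------------------------------------------------------------------
# centerline generators
# --------------------------------------------------------------------------

def _arc_params(arc_length: float, spacing: float) -> np.ndarray:
    n_full = int(np.floor(arc_length / spacing + 1e-9))
    s = spacing * np.arange(n_full + 1)
    if arc_length - s[-1] > 1e-9 * max(1.0, arc_length):
        s = np.append(s, arc_length)
    else:
        s[-1] = arc_length
    return s


def make_helix_centerline(spec: HelixSpec) -> Centerline:
    """Points exactly on the helix, spaced uniformly in arc length.

    Ground-truth curvature and torsion (a/(a^2+b^2), b/(a^2+b^2)) are
    attached as metadata for convergence testing.
    """
    c2 = spec.a**2 + spec.b**2
    s = _arc_params(spec.arc_length, spec.spacing)
    t = s / np.sqrt(c2)
    pts = np.column_stack([spec.a * np.cos(t), spec.a * np.sin(t), spec.b * t])
    meta = {
        "kappa_true": spec.a / c2,
        "tau_true": spec.b / c2,
        "arc_params": s,
    }
    return Centerline(pts, metadata=meta)


def _frenet_ode_step(state: np.ndarray, h: float, kfun, tfun, s: float) -> np.ndarray:
    """One RK4 step of C'=T, T'=kN, N'=-kT+tB, B'=-tN; state rows C,T,N,B."""

    def rhs(st: np.ndarray, si: float) -> np.ndarray:
        C, T, N, B = st
        k, tau = kfun(si), tfun(si)
        return np.stack([T, k * N, -k * T + tau * B, -tau * N])

    k1 = rhs(state, s)
    k2 = rhs(state + 0.5 * h * k1, s + 0.5 * h)
    k3 = rhs(state + 0.5 * h * k2, s + 0.5 * h)
    k4 = rhs(state + h * k3, s + h)
    out = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    # re-orthonormalize the frame to stop drift
    T = out[1] / np.linalg.norm(out[1])
    N = out[2] - (out[2] @ T) * T
    N /= np.linalg.norm(N)
    out[1], out[2], out[3] = T, N, np.cross(T, N)
    return out


def _cos2_bump(s: np.ndarray | float, center: float, width: float) -> np.ndarray:
    """cos^2 window of full width ``width`` centered at ``center``; peak 1."""
    x = (np.asarray(s, float) - center) / width
    out = np.where(np.abs(x) < 0.5, np.cos(np.pi * x) ** 2, 0.0)
    return out


def make_multibend_centerline(
    bends: Sequence[BendSpec],
    spacing: float = 0.15,
    seed: int = 0,
    transition_length: float = 8.0,
    length_jitter: float = 0.0,
) -> Centerline:
    """Composite multi-bend curve with flankable torsion peaks.

    The curve is defined by smooth curvature and torsion profiles and
    obtained by integrating the Frenet-Serret equations:

    * kappa(s): a small positive baseline plus one cos^2 bump per bend
      (peak at the bend center, full width = the bend arc length);
    * tau(s): a cos^2 bump at the center of each inter-bend transition,
      scaled so its integral equals the bend's twist angle.  The entry
      transition carries the first bend's twist and the exit transition
      repeats the last bend's twist, so n bends with nonzero twists give
      n+1 torsion peaks interleaving the n curvature peaks.

    Ground truth (curvature-peak / torsion-peak abscissae, bend
    boundaries, the integrated frames and profiles) is attached as
    metadata.  ``length_jitter`` randomly perturbs segment lengths by up
    to that relative fraction (seeded), to diversify fixture sets.
    """
    bends = list(bends)
    if len(bends) == 0:
        raise ValueError("need at least one bend")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)

    n = len(bends)
    trans = np.full(n + 1, float(transition_length))
    barc = np.array([b.bend_arc_length for b in bends], float)
    if length_jitter > 0:
        trans *= 1.0 + rng.uniform(-length_jitter, length_jitter, n + 1)
        barc *= 1.0 + rng.uniform(-length_jitter, length_jitter, n)

    # segment layout: trans_0, bend_0, trans_1, bend_1, ..., trans_n
    seg_len: list[float] = []
    for i in range(n):
        seg_len.append(trans[i])
        seg_len.append(barc[i])
    seg_len.append(trans[n])
    starts = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = starts[-1]

    bend_centers = np.array([starts[2 * i + 1] + barc[i] / 2 for i in range(n)])
    trans_centers = np.array([starts[2 * i] + trans[i] / 2 for i in range(n)]
                             + [starts[2 * n] + trans[n] / 2])

    peak_k = np.array([b.peak_curvature for b in bends], float)
    twist_rad = np.radians([b.twist_angle for b in bends])
    twist_per_trans = np.concatenate([twist_rad, [twist_rad[-1]]])
    tau_width = 0.8 * trans  # keep the bump inside its transition
    tau_amp = np.where(tau_width > 0, twist_per_trans / (tau_width / 2.0), 0.0)

    def kappa_of(s: float) -> float:
        k = BASELINE_KAPPA
        for i in range(n):
            k += (peak_k[i] - BASELINE_KAPPA) * _cos2_bump(s, bend_centers[i], barc[i])
        return float(k)

    def tau_of(s: float) -> float:
        t = 0.0
        for j in range(n + 1):
            t += tau_amp[j] * _cos2_bump(s, trans_centers[j], tau_width[j])
        return float(t)

    s_grid = _arc_params(total, spacing)
    state = np.stack([np.zeros(3),
                      np.array([1.0, 0.0, 0.0]),
                      np.array([0.0, 1.0, 0.0]),
                      np.array([0.0, 0.0, 1.0])])
    pts = np.empty((len(s_grid), 3))
    frames_t = np.empty_like(pts)
    frames_n = np.empty_like(pts)
    frames_b = np.empty_like(pts)
    pts[0], frames_t[0], frames_n[0], frames_b[0] = state
    for i in range(1, len(s_grid)):
        h = s_grid[i] - s_grid[i - 1]
        state = _frenet_ode_step(state, h, kappa_of, tau_of, s_grid[i - 1])
        pts[i], frames_t[i], frames_n[i], frames_b[i] = state

    torsion_peaks = trans_centers[np.abs(twist_per_trans) > 1e-12]
    bounds = [(trans_centers[i], trans_centers[i + 1]) for i in range(n)]
    meta = {
        "curvature_peaks": bend_centers,
        "torsion_peaks": torsion_peaks,
        "bend_bounds": bounds,
        "bend_peak_curvature": peak_k,
        "segment_lengths": np.asarray(seg_len),
        "total_arc_length": total,
        "gt_kappa": np.array([kappa_of(s) for s in s_grid]),
        "gt_tau": np.array([tau_of(s) for s in s_grid]),
        "gt_frames": {"t": frames_t, "n": frames_n, "b": frames_b},
        "arc_params": s_grid,
    }
    return Centerline(pts, metadata=meta)


# --------------------------------------------------------------------------
# flow parameterization
# --------------------------------------------------------------------------

def inflow_from_area(A: float, T: float) -> float:
    """Cycle-averaged inflow rate Q = 48.21 A^1.84 / T.

    Parameters
    ----------
    A : inlet cross-sectional area [cm^2]
    T : cardiac period [s]

    Returns
    -------
    Q : flow rate [ml/s]
    """
    if not A > 0:
        raise ValueError("inlet area A must be positive")
    if not T > 0:
        raise ValueError("cardiac period T must be positive")
    return INFLOW_COEFF * A**INFLOW_AREA_EXP / T


def murray_split(outlet_radii: Sequence[float], exponent: float = 3.0) -> np.ndarray:
    """Power-law outlet flow split: fraction_i = r_i^m / sum_j r_j^m.

    The classical Murray exponent is 3; it is configurable because
    measured cerebral-artery splits are often fit with other exponents.
    """
    r = np.asarray(outlet_radii, float)
    if r.size == 0:
        raise ValueError("need at least one outlet radius")
    if np.any(r <= 0):
        raise ValueError("outlet radii must be positive")
    if not exponent > 0:
        raise ValueError("exponent must be positive")
    w = r**exponent
    return w / w.sum()


def mean_axial_velocity(Q: float, R: float) -> float:
    """Section-mean axial velocity [m/s] for flow Q [ml/s] in a tube of radius R [mm].

    1 ml/s = 1e-6 m^3/s and 1 mm^2 = 1e-6 m^2, so the factors cancel:
    U = Q / (pi R^2) with these units.
    """
    return Q / (np.pi * R**2)


def secondary_amplitude(flow: FlowSpec, kappa: float, R: float, U: float) -> float:
    """Vortex-pair amplitude A_sec = c * kappa * R * U [m/s]."""
    return flow.coupling_c * kappa * R * U


def _vortex_pair(rho: np.ndarray, theta: np.ndarray, A: np.ndarray):
    """In-plane velocity of the stream function psi = A rho (1-rho^2)^2 sin(theta).

    v_rho  = (1/rho) dpsi/dtheta = A (1-rho^2)^2 cos(theta)
    v_theta = -dpsi/drho         = -A (1-rho^2)(1-5 rho^2) sin(theta)

    Both vanish at the wall (rho=1); v_theta also vanishes at the
    centerline point, keeping the field regular there.
    """
    one = 1.0 - rho**2
    v_rho = A * one**2 * np.cos(theta)
    v_theta = -A * one * (1.0 - 5.0 * rho**2) * np.sin(theta)
    return v_rho, v_theta


def make_flow_field(
    centerline: Centerline,
    frames,
    radius_profile: np.ndarray,
    flow: FlowSpec,
    n_rho: int = 8,
    n_theta: int = 16,
    stride: int = 1,
    secondary_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic velocity point cloud inside the lumen.

    At each sampled cross-section the axial velocity is the parabolic
    profile 2 U (1 - rho^2) along the local tangent with
    U = Q / (pi R^2), and the secondary velocity is the curvature-scaled
    vortex pair of :func:`_vortex_pair` with amplitude
    ``coupling_c * kappa * R * U`` (theta measured from the local Frenet
    normal).  The velocity is exactly zero on the wall ring (rho = 1)
    before noise; i.i.d. Gaussian noise of std ``noise_sigma`` is added
    per component using ``flow.seed``.

    ``secondary_scale`` optionally multiplies the vortex amplitude per
    centerline point — the population generator uses it to emulate
    upstream-history effects that make the secondary-flow strength of a
    real bend deviate from its local curvature.

    Returns ``(points, velocities)`` with shapes (m, 3) in mm and m/s.
    """
    R = np.asarray(radius_profile, float)
    if len(R) != len(centerline) or len(frames.t) != len(centerline):
        raise ValueError("centerline, frames and radius profile lengths must match")
    if np.any(R <= 0):
        raise ValueError("radius profile must be positive")

    idx = np.arange(len(centerline))[::stride]
    idx = idx[frames.valid[idx]]
    if idx.size == 0:
        raise ValueError("no valid frame points to build the field on")

    rho = np.arange(1, n_rho + 1) / n_rho  # (0, 1], includes the wall ring
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    rho_g, theta_g = np.meshgrid(rho, theta, indexing="ij")
    rho_g = rho_g.ravel()
    theta_g = theta_g.ravel()

    pts_all, vel_all = [], []
    for i in idx:
        p, t, nvec, bvec = centerline.points[i], frames.t[i], frames.n[i], frames.b[i]
        Ri = R[i]
        U = mean_axial_velocity(flow.Q, Ri)
        A = secondary_amplitude(flow, float(frames.kappa[i]), Ri, U)
        if secondary_scale is not None:
            A *= float(secondary_scale[i])
        e_r = np.outer(np.cos(theta_g), nvec) + np.outer(np.sin(theta_g), bvec)
        e_t = np.outer(-np.sin(theta_g), nvec) + np.outer(np.cos(theta_g), bvec)
        pos = p + (rho_g * Ri)[:, None] * e_r
        v_ax = 2.0 * U * (1.0 - rho_g**2)
        v_r, v_t = _vortex_pair(rho_g, theta_g, A)
        vel = v_ax[:, None] * t + v_r[:, None] * e_r + v_t[:, None] * e_t
        # centerline sample: pure axial peak velocity
        pts_all.append(np.vstack([p, pos]))
        vel_all.append(np.vstack([2.0 * U * t, vel]))

    points = np.concatenate(pts_all)
    velocities = np.concatenate(vel_all)
    if flow.noise_sigma > 0:
        rng = np.random.default_rng(flow.seed)
        velocities = velocities + rng.normal(0.0, flow.noise_sigma, velocities.shape)
    return points, velocities


# --------------------------------------------------------------------------
# population generator
# --------------------------------------------------------------------------

#: study-condition defaults for the synthetic cohort (see docs/methods.md)
POPULATION_DEFAULTS = {
    "n_bends": 3,
    "kappa_mu": 0.20,      # per-bend peak curvature mean [1/mm]
    "kappa_sigma": 0.10,   # per-bend peak curvature std [1/mm]
    "kappa_min": 0.05,     # truncation floor [1/mm]
    "effect": 0.10,        # A-bend curvature shift [1/mm]
    "bend_arc_mm": 15.0,
    "transition_mm": 8.0,
    "radius_mm": 2.3,      # mean lumen radius
    "radius_sd_mm": 0.15,
    "radius_wobble": 0.18, # relative sinusoidal taper amplitude
    "secondary_jitter": 0.30,  # sd of the per-bend log amplitude multiplier
    "cardiac_period_s": 0.8,
    "spacing_mm": 0.25,
    "coupling_c": 1.0,
    "noise_sigma": 0.002,  # m/s
    "neck_half_mm": 2.0,
    "twist_deg_range": (15.0, 40.0),
}

ORIENTATION_ANGLES = {"out": 0.0, "top": 90.0, "tilted": 45.0}


def make_population(
    n_cases: int,
    effect: float | None = None,
    flow: FlowSpec | None = None,
    seed: int = 0,
    with_fields: bool = True,
    **overrides,
) -> list[SyntheticCase]:
    """Generate a synthetic cohort of multi-bend cases.

    Each case has three bends (the typical count of distal ICA branch
    sections); one bend per case, chosen at random, is designated
    aneurysmal and draws its peak curvature from a distribution shifted
    upward by ``effect`` [1/mm].  The aneurysm direction is assigned one
    of the three orientation classes (out / top / tilted) uniformly at
    random, expressed in the local Frenet frame at the bend's curvature
    peak.  Everything (geometry, flow noise, annotations) derives from
    ``seed``; the same seed reproduces the population bitwise.

    ``flow`` overrides the coupling/noise template; its Q is replaced by
    the inflow scaling law evaluated at each case's inlet area.
    ``with_fields=False`` skips velocity-cloud generation (geometry-only
    studies such as landmarking benchmarks).
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    p = dict(POPULATION_DEFAULTS)
    p.update(overrides)
    if effect is None:
        effect = p["effect"]
    rng = np.random.default_rng(seed)
    classes = list(ORIENTATION_ANGLES)

    cases: list[SyntheticCase] = []
    for ci in range(n_cases):
        nb = p["n_bends"]
        kappas = rng.normal(p["kappa_mu"], p["kappa_sigma"], nb)
        kappas = np.maximum(kappas, p["kappa_min"])
        a_idx = int(rng.integers(nb))
        kappas[a_idx] += effect
        lo, hi = p["twist_deg_range"]
        twists = rng.uniform(lo, hi, nb) * rng.choice([-1.0, 1.0], nb)
        bends = [BendSpec(float(k), p["bend_arc_mm"], float(tw))
                 for k, tw in zip(kappas, twists)]
        cl = make_multibend_centerline(
            bends, spacing=p["spacing_mm"], seed=int(rng.integers(2**31 - 1)),
            transition_length=p["transition_mm"], length_jitter=0.1)

        s = cl.abscissa
        R0 = max(1.5, rng.normal(p["radius_mm"], p["radius_sd_mm"]))
        phase = rng.uniform(0, 2 * np.pi)
        radius = R0 * (1.0 + p["radius_wobble"]
                       * np.sin(2 * np.pi * 1.5 * s / s[-1] + phase))
        cl = cl.with_radius(radius)

        A_cm2 = np.pi * (R0 / 10.0) ** 2
        Q = inflow_from_area(A_cm2, p["cardiac_period_s"])
        template = flow if flow is not None else FlowSpec(
            Q=Q, coupling_c=p["coupling_c"], noise_sigma=p["noise_sigma"])
        case_flow = dataclasses.replace(
            template, Q=Q, seed=int(rng.integers(2**31 - 1)))

        gt_frames = cl.metadata["gt_frames"]

        # aneurysm annotation at the aneurysmal bend's curvature peak
        peak_s = cl.metadata["curvature_peaks"][a_idx]
        pk = int(np.argmin(np.abs(cl.metadata["arc_params"] - peak_s)))
        ocls = classes[int(rng.integers(len(classes)))]
        alpha = np.radians(ORIENTATION_ANGLES[ocls])
        direction = np.cos(alpha) * gt_frames["n"][pk] + np.sin(alpha) * gt_frames["b"][pk]

        # per-bend secondary-strength multiplier: real bends deviate from
        # the local-curvature scaling through upstream-history effects
        sec_scale = np.ones(len(cl))
        if p["secondary_jitter"] > 0:
            borders = [bb[0] for bb in cl.metadata["bend_bounds"]]
            borders.append(cl.metadata["bend_bounds"][-1][1])
            mult = np.exp(rng.normal(0.0, p["secondary_jitter"], nb + 2))
            region = np.searchsorted(np.asarray(borders), s)
            sec_scale = mult[region]

        field_pts = field_vel = None
        if with_fields:
            frames = _PrescribedFrames(
                t=gt_frames["t"], n=gt_frames["n"], b=gt_frames["b"],
                kappa=cl.metadata["gt_kappa"],
                valid=np.ones(len(cl), bool))
            field_pts, field_vel = make_flow_field(
                cl, frames, radius, case_flow,
                n_rho=p.get("field_n_rho", 7),
                n_theta=p.get("field_n_theta", 24),
                stride=p.get("field_stride", 2),
                secondary_scale=sec_scale)

        gt = {
            "bend_bounds": cl.metadata["bend_bounds"],
            "curvature_peaks": cl.metadata["curvature_peaks"],
            "bend_peak_curvature": cl.metadata["bend_peak_curvature"],
            "flow": case_flow,
            "orientation_class": ocls,
        }
        cases.append(SyntheticCase(
            case_id=f"case{ci:03d}",
            centerline=cl,
            field_points=field_pts,
            field_velocities=field_vel,
            aneurysm_bend_index=a_idx,
            aneurysm_direction=direction,
            neck_start_abscissa=float(peak_s - p["neck_half_mm"]),
            neck_end_abscissa=float(peak_s + p["neck_half_mm"]),
            orientation_class=ocls,
            ground_truth=gt,
        ))
    return cases


@dataclass
class _PrescribedFrames:
    """Frame container mirroring FrenetFrameSet for the generator's ground truth."""

    t: np.ndarray
    n: np.ndarray
    b: np.ndarray
    kappa: np.ndarray
    valid: np.ndarray
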