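"""Slicing, interpolation, velocity decomposition and ROI averaging."""

import numpy as np
import pytest

from secflow import (
    FlowSpec,
    aneurysm_theta,
    classify_orientation,
    decompose,
    frenet,
    make_flow_field,
    make_population,
    make_slices,
    near_wall_threshold,
    roi_average,
    sample_velocity,
    straighten,
)
from secflow.pipeline import analyze_case
from secflow.sections import CrossSection

from conftest import poiseuille, straight_tube


# frame, center and frozen expected components for the 5-sample oracle:
# computed once by direct scalar evaluation of the axial/radial/
# circumferential projection formulas, independent of the package code.
ORACLE_T = np.array([1 / 3, 2 / 3, 2 / 3])
ORACLE_N = np.array([2 / 3, 1 / 3, -2 / 3])
ORACLE_B = np.array([-2 / 3, 2 / 3, -1 / 3])
ORACLE_P = np.array([1.0, -2.0, 0.5])
ORACLE_SAMPLES = [
    # (point, velocity, v_ax, v_rad, v_cir)
    ([1.3333333333333333, -1.5333333333333334, -0.1333333333333333],
     [0.2, -0.1, 0.4],
     [0.088888888888888878, 0.17777777777777776, 0.17777777777777776],
     [-0.10654490106544903, -0.14916286149162869, 0.20243531202435322],
     [0.21765601217656017, -0.1286149162861491, 0.019786910197869045]),
    ([0.066666666666666763, -1.5666666666666664, 0.53333333333333321],
     [0.0, 0.3, -0.2],
     [0.022222222222222216, 0.044444444444444432, 0.044444444444444432],
     [-0.10859538784067092, 0.050419287211740098, 0.0038784067085953764],
     [0.086373165618448711, 0.20513626834381543, -0.24832285115303981]),
    ([1.7999999999999998, -2.7999999999999998, 0.89999999999999991],
     [0.5, 0.5, 0.5],
     [0.27777777777777773, 0.55555555555555547, 0.55555555555555547],
     [0.1111111111111111, -0.1111111111111111, 0.055555555555555552],
     [0.11111111111111116, 0.055555555555555636, -0.11111111111111102]),
    ([1.0, -0.89999999999999991, -0.60000000000000009],
     [-0.3, 0.2, 0.1],
     [0.033333333333333333, 0.066666666666666666, 0.066666666666666666],
     [0.0, 0.050000000000000003, -0.050000000000000003],
     [-0.33333333333333331, 0.083333333333333356, 0.083333333333333343]),
    ([0.80000000000000004, -2.5, 1.0999999999999999],
     [0.1, 0.0, -0.6],
     [-0.1222222222222222, -0.24444444444444441, -0.24444444444444441],
     [0.11692307692307694, 0.29230769230769238, -0.35076923076923083],
     [0.10529914529914527, -0.047863247863247971, -0.004786324786324736]),
]


def oracle_slice():
    pts = np.array([s[0] for s in ORACLE_SAMPLES])
    rel = pts - ORACLE_P
    rho = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel @ ORACLE_B, rel @ ORACLE_N)
    s = CrossSection(index=0, abscissa=0.0, center=ORACLE_P.copy(),
                     t=ORACLE_T.copy(), n=ORACLE_N.copy(), b=ORACLE_B.copy(),
                     rho=rho / rho.max(), theta=theta,
                     wall=np.full(len(pts), rho.max()), points=pts)
    s.v = np.array([smp[1] for smp in ORACLE_SAMPLES], float)
    s.mask = np.ones(len(pts), bool)
    return s


class TestMakeSlices:
    def test_planes_perpendicular_to_straight_axis(self):
        c, frames = straight_tube()
        slices = make_slices(c, frames, n_rho=4, n_theta=8)
        for s in slices:
            assert np.allclose(s.points[:, 2], s.center[2], atol=1e-12)

    def test_sample_count(self):
        c, frames = straight_tube()
        s = make_slices(c, frames, n_rho=16, n_theta=64)[0]
        assert len(s.points) == 1024

    def test_slice_plane_contains_normal_on_curved_tube(self, circle):
        fr = frenet(circle)
        circle = circle.with_radius(np.full(len(circle), 2.0))
        slices = make_slices(circle, fr, n_rho=4, n_theta=8)
        for s in slices[::10]:
            rel = s.points - s.center
            assert np.abs(rel @ s.t).max() < 1e-8

    def test_wall_scaling_uses_radius(self):
        c, frames = straight_tube(radius=3.0)
        s = make_slices(c, frames, n_rho=4, n_theta=8)[0]
        r = np.linalg.norm(s.points - s.center, axis=1)
        assert r.max() == pytest.approx(3.0, abs=1e-12)


class TestSampleVelocity:
    def test_constant_field(self):
        c, frames = straight_tube()
        s = make_slices(c, frames, n_rho=4, n_theta=8)[5]
        rng = np.random.default_rng(0)
        pts = rng.uniform(-3, 3, (4000, 3)) + np.array([0, 0, 2.5])
        vel = np.tile([0.1, -0.2, 0.3], (4000, 1))
        sample_velocity(s, pts, vel)
        assert np.allclose(s.v[s.mask], [0.1, -0.2, 0.3], atol=1e-12)

    def test_exact_at_nodes(self):
        c, frames = straight_tube()
        s = make_slices(c, frames, n_rho=4, n_theta=8)[3]
        pts = np.vstack([s.points[7], np.random.default_rng(1).uniform(-3, 3, (500, 3))])
        vel = np.arange(pts.size, dtype=float).reshape(pts.shape)
        sample_velocity(s, pts, vel)
        assert np.allclose(s.v[7], vel[0], atol=1e-14)

    def test_linear_field_refinement(self):
        M = np.array([[0.1, 0.2, 0.0], [0.0, -0.3, 0.1], [0.2, 0.0, 0.4]])
        c, frames = straight_tube()
        s = make_slices(c, frames, n_rho=4, n_theta=8)[5]
        errs = []
        for n_cloud in (2000, 16000):
            rng = np.random.default_rng(4)
            pts = rng.uniform(-3, 3, (n_cloud, 3)) + np.array([0, 0, 2.5])
            sample_velocity(s, pts, pts @ M.T)
            errs.append(np.abs(s.v[s.mask] - s.points[s.mask] @ M.T).max())
        assert errs[1] < errs[0]

    def test_empty_field_rejected(self, tube_slice):
        with pytest.raises(ValueError):
            sample_velocity(tube_slice, np.empty((0, 3)), np.empty((0, 3)))


class TestDecompose:
    def test_pure_axial_flow(self, tube_slice):
        tube_slice.v = np.tile(tube_slice.t * 0.4, (len(tube_slice.points), 1))
        decompose(tube_slice)
        assert np.abs(tube_slice.v_rad).max() < 1e-14
        assert np.abs(tube_slice.v_cir).max() < 1e-14

    def test_rigid_rotation_is_pure_circumferential(self, tube_slice):
        omega = 2.0
        rel = tube_slice.points - tube_slice.center
        tube_slice.v = omega * np.cross(tube_slice.t, rel)
        decompose(tube_slice)
        assert np.abs(tube_slice.v_ax).max() < 1e-12
        assert np.abs(tube_slice.v_rad).max() < 1e-12
        r = np.linalg.norm(rel, axis=1)
        assert np.allclose(np.linalg.norm(tube_slice.v_cir, axis=1), omega * r,
                           atol=1e-12)

    def test_components_reassemble_input(self, tube_slice):
        rng = np.random.default_rng(3)
        tube_slice.v = rng.normal(0, 0.3, (len(tube_slice.points), 3))
        decompose(tube_slice)
        back = tube_slice.v_ax + tube_slice.v_rad + tube_slice.v_cir
        ok = tube_slice.polar_ok
        assert np.abs(back[ok] - tube_slice.v[ok]).max() < 1e-12

    def test_energy_conservation(self, tube_slice):
        rng = np.random.default_rng(9)
        tube_slice.v = rng.normal(0, 0.3, (len(tube_slice.points), 3))
        decompose(tube_slice)
        ok = tube_slice.polar_ok
        lhs = (tube_slice.v[ok] ** 2).sum()
        rhs = sum(((arr[ok] ** 2).sum()
                   for arr in (tube_slice.v_ax, tube_slice.v_rad, tube_slice.v_cir)))
        assert abs(lhs - rhs) < 1e-10 * lhs

    def test_five_sample_hand_oracle(self):
        s = oracle_slice()
        decompose(s)
        for i, (_, _, vax, vrad, vcir) in enumerate(ORACLE_SAMPLES):
            assert np.abs(s.v_ax[i] - vax).max() < 1e-12
            assert np.abs(s.v_rad[i] - vrad).max() < 1e-12
            assert np.abs(s.v_cir[i] - vcir).max() < 1e-12


class TestStraighten:
    def test_frame_maps_to_axes(self, tube_slice):
        coords, R, p = straighten(tube_slice)
        assert np.allclose(R @ tube_slice.n, [1, 0, 0], atol=1e-12)
        assert np.allclose(R @ tube_slice.b, [0, 1, 0], atol=1e-12)
        assert np.allclose(R @ tube_slice.t, [0, 0, 1], atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_isometry_and_inverse(self):
        s = oracle_slice()
        coords, R, p = straighten(s)
        d_before = np.linalg.norm(s.points[:, None] - s.points[None, :], axis=-1)
        d_after = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(d_before - d_after).max() < 1e-12
        restored = coords @ R + p
        assert np.abs(restored - s.points).max() < 1e-12


class TestOrientation:
    def test_along_normal_is_out(self, tube_slice):
        oc = classify_orientation(tube_slice.n, [tube_slice])
        assert oc.label == "out"
        assert oc.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_along_binormal_is_top(self, tube_slice):
        oc = classify_orientation(tube_slice.b, [tube_slice])
        assert oc.label == "top"
        assert oc.angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_is_tilted(self, tube_slice):
        d = (tube_slice.n + tube_slice.b) / np.sqrt(2)
        oc = classify_orientation(d, [tube_slice])
        assert oc.label == "tilted"
        assert oc.angle_deg == pytest.approx(45.0, abs=1e-9)

    def test_tangent_direction_rejected(self, tube_slice):
        with pytest.raises(ValueError):
            classify_orientation(tube_slice.t, [tube_slice])

    def test_aneurysm_theta(self, tube_slice):
        assert aneurysm_theta(tube_slice.n, tube_slice) == pytest.approx(0.0)
        assert aneurysm_theta(tube_slice.b, tube_slice) == pytest.approx(np.pi / 2)


class TestRoi:
    def test_near_wall_threshold_closed_form(self):
        assert near_wall_threshold(0.5) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_axisymmetric_field_has_equal_sides(self, tube_slice):
        s = poiseuille(tube_slice)
        decompose(s)
        a, o = roi_average(s, theta_center=0.3)
        assert a.count > 0 and o.count > 0
        for qa, qo in [(a.mean_v, o.mean_v), (a.mean_v_ax, o.mean_v_ax)]:
            assert abs(qa - qo) <= 1e-9 * max(qa, 1e-300)

    def test_sector_width_and_complementarity(self, tube_slice):
        s = poiseuille(tube_slice)
        decompose(s)
        a, o = roi_average(s, theta_center=0.0, sector_deg=180.0)
        band = (s.rho >= near_wall_threshold() - 1e-12) & s.polar_ok
        assert a.count + o.count == int(band.sum())

    def test_cir_mean_scales_linearly_with_amplitude(self, circle):
        fr = frenet(circle)
        R = np.full(len(circle), 2.0)
        circle = circle.with_radius(R)
        means = []
        for cc in (0.5, 1.0):
            flow = FlowSpec(Q=3.0, coupling_c=cc, noise_sigma=0.0)
            pts, vel = make_flow_field(circle, fr, R, flow, n_rho=8, n_theta=24)
            slices = make_slices(circle, fr, n_rho=8, n_theta=24, stride=30)
            sample_velocity(slices, pts, vel, k=4)
            decompose(slices)
            s = slices[1]
            a, _ = roi_average(s, theta_center=0.0)
            means.append(a.mean_v_cir)
        assert means[1] / means[0] == pytest.approx(2.0, abs=1e-6)

    def test_bad_parameters_rejected(self, tube_slice):
        s = poiseuille(tube_slice)
        decompose(s)
        with pytest.raises(ValueError):
            roi_average(s, 0.0, sector_deg=200.0)
        with pytest.raises(ValueError):
            roi_average(s, 0.0, wall_fraction=1.5)


class TestRotationEquivariance:
    def test_roi_means_invariant_under_rigid_motion(self):
        from secflow.synthetic import SyntheticCase

        case = make_population(2, seed=77)[0]
        res = analyze_case(case)

        # a rigid rotation + translation applied to everything
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        shift = np.array([5.0, -3.0, 2.0])
        from secflow import Centerline
        cl2 = Centerline(case.centerline.points @ Q.T + shift,
                         radius=case.centerline.radius)
        case2 = SyntheticCase(
            case_id="rot", centerline=cl2,
            field_points=case.field_points @ Q.T + shift,
            field_velocities=case.field_velocities @ Q.T,
            aneurysm_bend_index=case.aneurysm_bend_index,
            aneurysm_direction=case.aneurysm_direction @ Q.T,
            neck_start_abscissa=case.neck_start_abscissa,
            neck_end_abscissa=case.neck_end_abscissa,
            orientation_class=case.orientation_class)
        res2 = analyze_case(case2)
        for col in ("mean_v", "mean_v_ax", "mean_v_cir", "mean_v_rad"):
            a = res["slice_df"][col].to_numpy()
            b = res2["slice_df"][col].to_numpy()
            assert np.abs(a - b).max() < 1e-9
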