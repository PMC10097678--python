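import numpy as np
import pytest

from proprio import kinematics as kin
from proprio import synthetic_data as sd


class TestPantograph:
    def test_forward_kinematics_hand_geometry(self):
        # d=2, lp=1, ld=2, both motors straight up: elbows at (0,1), (2,1);
        # circle intersection at (1, 1+sqrt(3)) by hand geometry
        geom = kin.PantographGeometry(2.0, 1.0, 2.0)
        p = kin.forward_kinematics(geom, kin.MotorAngles(np.pi / 2, np.pi / 2))
        assert np.allclose(p, [1.0, 1.0 + np.sqrt(3.0)], atol=1e-12)

    def test_mirror_symmetry_puts_endpoint_on_midline(self):
        geom = kin.PantographGeometry(2.0, 1.0, 2.0)
        for tl in (0.6, 1.0, 1.4):
            p = kin.forward_kinematics(geom, kin.MotorAngles(tl, np.pi - tl))
            assert p[0] == pytest.approx(geom.motor_separation_d / 2, abs=1e-12)

    def test_ik_recovers_working_mode_angles(self):
        geom = kin.PantographGeometry(2.0, 1.0, 2.0)
        ang = kin.inverse_kinematics(geom, (1.0, 1.0 + np.sqrt(3.0)))
        assert ang.theta_left == pytest.approx(np.pi / 2, abs=1e-9)
        assert ang.theta_right == pytest.approx(np.pi / 2, abs=1e-9)

    def test_ik_symmetric_on_midline(self):
        geom = kin.PantographGeometry()
        ang = kin.inverse_kinematics(geom, (1.0, 3.5))
        assert ang.theta_right == pytest.approx(np.pi - ang.theta_left, abs=1e-9)

    def test_fk_ik_position_round_trip(self, rng):
        geom = kin.PantographGeometry()
        n_ok = 0
        while n_ok < 100:
            p = rng.uniform([-1.5, 1.0], [3.5, 4.5])
            try:
                ang = kin.inverse_kinematics(geom, p)
            except kin.UnreachableError:
                continue
            p2 = kin.forward_kinematics(geom, ang)
            assert np.hypot(*(p2 - p)) < 1e-9
            n_ok += 1

    def test_unreachable_target_names_chain(self):
        geom = kin.PantographGeometry()
        with pytest.raises(kin.UnreachableError, match="left chain"):
            kin.inverse_kinematics(geom, (-6.0, 0.5))

    def test_maximal_reach_boundary(self):
        # symmetric target at full extension of both chains: links collinear
        geom = kin.PantographGeometry(2.0, 2.0, 3.0)
        r_max = geom.proximal_link_lp + geom.distal_link_ld
        half_d = geom.motor_separation_d / 2
        target = np.array([half_d, np.sqrt(r_max**2 - half_d**2)])
        ang = kin.inverse_kinematics(geom, target)
        # left elbow lies on the hub-target line (zero interior angle)
        elbow = geom.proximal_link_lp * np.array(
            [np.cos(ang.theta_left), np.sin(ang.theta_left)]
        )
        cross = elbow[0] * target[1] - elbow[1] * target[0]
        assert abs(cross) < 1e-9


class TestTrajectory:
    def test_closed_form_duration(self):
        # 7 mm at 2 cm/s with 20 cm/s^2: d/v + v/a = 0.35 + 0.1 = 0.45 s
        traj = kin.trapezoid_trajectory((0, 0), (0.7, 0), 2.0, 20.0)
        assert traj.times_s[-1] == pytest.approx(0.45, abs=1e-9)

    def test_rectangular_limit(self):
        traj = kin.trapezoid_trajectory((0, 0), (0.7, 0), 2.0, 1e9)
        assert traj.times_s[-1] == pytest.approx(0.35, abs=1e-3)

    def test_displacement_conservation(self, rng):
        for _ in range(5):
            end = rng.uniform(-1, 1, 2)
            if np.hypot(*end) < 0.05:
                continue
            traj = kin.trapezoid_trajectory((0, 0), end, 2.5, 15.0)
            travelled = float((traj.speed * np.diff(traj.times_s)).sum())
            assert travelled == pytest.approx(np.hypot(*end), rel=1e-3)

    def test_cruise_speed_equals_peak(self):
        traj = kin.trapezoid_trajectory((0, 0), (2.0, 0), 3.0, 30.0)
        assert np.max(np.abs(traj.speed)) == pytest.approx(3.0, rel=1e-6)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            kin.trapezoid_trajectory((1, 1), (1, 1), 2.0)


class TestTriangulation:
    def test_noiseless_exact_recovery(self):
        grid = [(0.2, 0.4), (-0.4, 1.0), (0.8, 0.8)]
        pix, truth, _ = sd.gen_stereo_scene(grid, pixel_noise_sd=0.0)
        cams = sd.default_stereo_cameras()
        for pixels, gt in zip(pix, truth):
            joints = kin.triangulate_joints(pixels, cams)
            assert np.abs(joints.as_array() - gt.as_array()).max() < 1e-9

    def test_camera_order_swap_changes_frame_consistently(self):
        grid = [(0.3, 0.6)]
        pix, truth, _ = sd.gen_stereo_scene(grid)
        P1, P2 = sd.default_stereo_cameras()
        j12 = kin.triangulate_joints(pix[0], (P1, P2))
        swapped = {k: (v[1], v[0]) for k, v in pix[0].items()}
        j21 = kin.triangulate_joints(swapped, (P2, P1))
        # same world frame is defined by the matrices, not their order
        assert np.abs(j12.as_array() - j21.as_array()).max() < 1e-9

    def test_noisy_error_matches_monte_carlo_oracle(self, rng):
        # brute-force reprojection Monte-Carlo at the same geometry
        grid = [(0.2, 0.4)]
        cams = sd.default_stereo_cameras()
        sigma = 0.5
        errs = []
        for k in range(200):
            pix, truth, _ = sd.gen_stereo_scene(grid, pixel_noise_sd=sigma, seed=k)
            j = kin.triangulate_joints(pix[0], cams)
            errs.append(np.linalg.norm(j.endpoint - truth[0].endpoint))
        median_err = np.median(errs)
        # oracle: independent replicate of the same experiment
        oracle = []
        for k in range(200, 400):
            pix, truth, _ = sd.gen_stereo_scene(grid, pixel_noise_sd=sigma, seed=k)
            j = kin.triangulate_joints(pix[0], cams)
            oracle.append(np.linalg.norm(j.endpoint - truth[0].endpoint))
        assert median_err == pytest.approx(np.median(oracle), rel=0.2)
        assert median_err < np.percentile(oracle, 99)


class TestSimilarityTransform:
    def test_known_transform_recovered(self, rng):
        src = rng.uniform(-2, 2, (8, 3))
        th = np.deg2rad(30.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        dst = 2.0 * src @ R.T + np.array([1.0, 2.0, 3.0])
        T = kin.fit_similarity_transform(src, dst)
        assert np.abs(T.rotation - R).max() < 1e-9
        assert T.scale == pytest.approx(2.0, abs=1e-9)
        assert np.abs(T.translation - [1, 2, 3]).max() < 1e-9
        assert T.residual_rms < 1e-9

    def test_identity_correspondence(self, rng):
        pts = rng.uniform(-1, 1, (5, 3))
        T = kin.fit_similarity_transform(pts, pts)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-9
        assert T.scale == pytest.approx(1.0, abs=1e-9)
        assert np.abs(T.translation).max() < 1e-9

    def test_mirrored_target_never_yields_reflection(self, rng):
        src = rng.uniform(-1, 1, (10, 3))
        dst = src.copy()
        dst[:, 0] *= -1  # reflection
        T = kin.fit_similarity_transform(src, dst)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert T.residual_rms > 0.1  # proper rotation cannot fit a mirror

    def test_apply_then_invert_is_identity(self, rng):
        src = rng.uniform(-1, 1, (6, 3))
        dst = 1.7 * src + np.array([0.5, -1.0, 2.0])
        T = kin.fit_similarity_transform(src, dst)
        pts = rng.uniform(-3, 3, (20, 3))
        back = T.inverse().apply(T.apply(pts))
        assert np.abs(back - pts).max() < 1e-10

    def test_collinear_source_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            kin.fit_similarity_transform(src, src)


class TestHumerusAngle:
    @pytest.mark.parametrize(
        "gleno,elbow,expected",
        [
            ((0, 0, 1), (0, 0, 0), 0.0),  # straight down
            ((0, 0, 0), (1, 0, 0), 90.0),  # horizontal lateral
            ((0, 0, 0), (-1, 0, -1), -45.0),  # down-medial
        ],
    )
    def test_reference_poses(self, gleno, elbow, expected):
        joints = kin.JointSet3D(
            scapulothoracic=np.zeros(3),
            glenohumeral=np.asarray(gleno, dtype=float),
            elbow=np.asarray(elbow, dtype=float),
            wrist=np.zeros(3),
            endpoint=np.zeros(3),
        )
        assert kin.humerus_azimuth_angle(joints) == pytest.approx(expected, abs=1e-12)

    def test_pure_anterior_humerus_undefined(self):
        joints = kin.JointSet3D(
            scapulothoracic=np.zeros(3),
            glenohumeral=np.zeros(3),
            elbow=np.array([0.0, 1.0, 0.0]),
            wrist=np.zeros(3),
            endpoint=np.zeros(3),
        )
        with pytest.raises(ValueError, match="undefined"):
            kin.humerus_azimuth_angle(joints)


class TestAngleMap:
    def _linear_field_map(self, a=3.0, b=-2.0):
        pts = [(x, y) for x in np.linspace(-1, 1, 6) for y in np.linspace(-1, 1, 6)]

        def joints_for(x, y):
            # humerus whose azimuth is exactly a*x + b*y degrees
            ang = np.deg2rad(a * x + b * y)
            return kin.JointSet3D(
                scapulothoracic=np.zeros(3),
                glenohumeral=np.zeros(3),
                elbow=np.array([np.sin(ang), 0.0, -np.cos(ang)]),
                wrist=np.zeros(3),
                endpoint=np.zeros(3),
            )

        return kin.build_angle_map([(p, joints_for(*p)) for p in pts]), a, b

    def test_nodes_reproduced_exactly(self):
        amap, a, b = self._linear_field_map()
        for x, y in [(-1, -1), (0.2, -0.6), (1, 1)]:
            assert amap((x, y)) == pytest.approx(a * x + b * y, abs=1e-9)

    def test_zero_distance_zero_delta(self):
        amap, _, _ = self._linear_field_map()
        assert kin.angle_change_for_displacement(amap, (0.1, 0.1), 45.0, 0.0) == 0.0

    def test_constant_field_zero_delta(self):
        pts = [(x, y) for x in (-1.0, 0.0, 1.0) for y in (-1.0, 0.0, 1.0)]
        joints = kin.JointSet3D(
            scapulothoracic=np.zeros(3),
            glenohumeral=np.zeros(3),
            elbow=np.array([0.5, 0.0, -0.5]),
            wrist=np.zeros(3),
            endpoint=np.zeros(3),
        )
        amap = kin.build_angle_map([(p, joints) for p in pts])
        delta = kin.angle_change_for_displacement(amap, (0.0, 0.0), 120.0, 5.0)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_matches_directional_derivative(self):
        amap, a, b = self._linear_field_map()
        for direction, dist_mm in [(0.0, 5.0), (90.0, 3.0), (210.0, 7.0)]:
            th = np.deg2rad(direction)
            expected = (a * np.cos(th) + b * np.sin(th)) * dist_mm / 10.0
            got = kin.angle_change_for_displacement(amap, (0.05, -0.05), direction, dist_mm)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_query_outside_hull_raises(self):
        amap, _, _ = self._linear_field_map()
        with pytest.raises(ValueError, match="outside"):
            amap((5.0, 5.0))
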