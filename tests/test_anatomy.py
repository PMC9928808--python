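"""Surface fits, bone frames, and joint-coordinate-system round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kneekin.anatomy import (
    BoneFrame,
    JointSingularityError,
    PF_JOINT_SPEC,
    SurfaceFitError,
    TF_JOINT_SPEC,
    build_femoral_frame,
    build_patellar_frame,
    build_tibial_frame,
    fit_cone,
    fit_cylinder,
    jcs_compose,
    jcs_decompose,
    principal_axes,
    reexpress_parameters,
    rigid_transform,
)
from kneekin.synthdata import sample_bone_surfaces


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return rigid_transform(R, rng.uniform(-50, 50, 3))


def random_params(rng):
    return np.array(
        [
            *rng.uniform(-20, 20, 3),
            rng.uniform(-100, 100),
            rng.uniform(-45, 45),
            rng.uniform(-80, 80),
        ]
    )


class TestFitCylinder:
    def cylinder_points(self, rng, radius=20.0, n=200):
        x = rng.uniform(-30, 30, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([x, radius * np.cos(phi), radius * np.sin(phi)])

    def test_noiseless_recovery(self, rng):
        pts = self.cylinder_points(rng)
        fit = fit_cylinder(pts)
        assert abs(fit.radius - 20.0) < 1e-8
        np.testing.assert_allclose(np.abs(fit.axis), [1, 0, 0], atol=1e-8)
        assert fit.axis[0] > 0  # deterministic sign

    def test_noisy_radius_within_monte_carlo_bound(self):
        sigma, n, reps = 0.1, 200, 20
        errs = []
        for seed in range(reps):
            r = np.random.default_rng(seed)
            pts = self.cylinder_points(r, n=n) + r.normal(0, sigma, (n, 3))
            errs.append(fit_cylinder(pts).radius - 20.0)
        # radius estimate is unbiased to O(sigma^2/R); mean error within
        # a few standard errors of zero
        assert abs(np.mean(errs)) < 4 * sigma / np.sqrt(n)

    def test_coplanar_points_rejected(self, rng):
        pts = np.column_stack([rng.normal(size=10), rng.normal(size=10), np.zeros(10)])
        with pytest.raises(SurfaceFitError, match="coplanar"):
            fit_cylinder(pts)


class TestFitCone:
    def cone_points(self, rng, half_angle_deg=5.0, n=300):
        t = rng.uniform(20, 120, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = t * np.tan(np.radians(half_angle_deg))
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), t])

    def test_noiseless_recovery(self, rng):
        pts = self.cone_points(rng)
        fit = fit_cone(pts)
        assert abs(fit.half_angle_deg - 5.0) < 1e-6
        np.testing.assert_allclose(fit.axis, [0, 0, 1], atol=1e-6)
        np.testing.assert_allclose(fit.apex, [0, 0, 0], atol=1e-5)

    def test_noisy_half_angle_within_bound(self):
        errs = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            pts = self.cone_points(r) + r.normal(0, 0.05, (300, 3))
            errs.append(fit_cone(pts).half_angle_deg - 5.0)
        assert abs(np.mean(errs)) < 0.05

    def test_cylinder_like_data_reports_small_half_angle(self, rng):
        x = rng.uniform(-30, 30, 200)
        phi = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([x, 15 * np.cos(phi), 15 * np.sin(phi)])
        fit = fit_cone(pts)
        assert fit.half_angle_deg < 0.5


class TestPrincipalAxes:
    def test_box_lattice_recovers_edges(self):
        g = np.mgrid[0:5, 0:9, 0:3].reshape(3, -1).T.astype(float)
        centroid, axes, moments = principal_axes(g)
        np.testing.assert_allclose(centroid, [2, 4, 1], atol=1e-12)
        # moments ascend; the longest box direction has the smallest moment
        assert abs(axes[:, 0] @ [0, 1, 0]) > 0.999

    def test_rotated_ellipsoid_recovers_rotation(self, rng):
        u = rng.normal(size=(2000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.uniform(0, 1, 2000) ** (1 / 3)
        pts = (u * r[:, None]) * np.array([30.0, 10.0, 20.0])
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        _, axes0, _ = principal_axes(pts)
        _, axes1, _ = principal_axes(
            pts @ R.T, hint_vectors=[R @ axes0[:, i] for i in range(3)]
        )
        np.testing.assert_allclose(axes1, R @ axes0, atol=1e-6)

    def test_sphere_is_ambiguous(self, rng):
        u = rng.normal(size=(5000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * (rng.uniform(0, 1, 5000) ** (1 / 3))[:, None]
        with pytest.raises(SurfaceFitError, match="degenerate"):
            principal_axes(pts, degeneracy_tol=0.05)


class TestBoneFrames:
    def test_canonical_femur_is_identity(self):
        fx = sample_bone_surfaces(seed=1)
        frame = build_femoral_frame(
            fx.condyle_points, fx.femoral_diaphysis_points, fx.landmarks["notch_apex"]
        )
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-8)

    def test_canonical_tibia_is_identity(self):
        fx = sample_bone_surfaces(seed=1)
        frame = build_tibial_frame(
            fx.tibial_diaphysis_points,
            fx.landmarks["plateau_centers"],
            fx.landmarks["eminence_midpoint"],
            fx.femur_frame.origin,
            proximal_hint=fx.landmarks["proximal_hint"],
        )
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-8)

    def test_patellar_frame_matches_ground_truth(self):
        fx = sample_bone_surfaces(seed=1)
        frame = build_patellar_frame(
            fx.patella_points, fx.landmarks["ridge_direction"], fx.landmarks["anterior_hint"]
        )
        np.testing.assert_allclose(frame.axes, fx.patella_frame.axes, atol=1e-8)
        np.testing.assert_allclose(frame.origin, fx.patella_frame.origin, atol=1e-8)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_equivariance_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        T = random_rigid(rng)
        fx0 = sample_bone_surfaces(seed=seed)
        fx1 = sample_bone_surfaces(seed=seed, transform=T)
        f0 = build_femoral_frame(
            fx0.condyle_points,
            fx0.femoral_diaphysis_points,
            fx0.landmarks["notch_apex"],
            right_hint=fx0.landmarks["right_hint"],
            proximal_hint=fx0.landmarks["proximal_hint"],
        )
        f1 = build_femoral_frame(
            fx1.condyle_points,
            fx1.femoral_diaphysis_points,
            fx1.landmarks["notch_apex"],
            right_hint=fx1.landmarks["right_hint"],
            proximal_hint=fx1.landmarks["proximal_hint"],
        )
        expected = f0.transformed(T)
        np.testing.assert_allclose(f1.axes, expected.axes, atol=1e-8)
        np.testing.assert_allclose(f1.origin, expected.origin, atol=1e-7)

    def test_noisy_femoral_axis_error_below_half_degree(self):
        angular_errors = []
        for seed in range(50):
            fx = sample_bone_surfaces(seed=seed, noise_sd=0.1)
            frame = build_femoral_frame(
                fx.condyle_points,
                fx.femoral_diaphysis_points,
                fx.landmarks["notch_apex"],
                right_hint=fx.landmarks["right_hint"],
                proximal_hint=fx.landmarks["proximal_hint"],
            )
            cosang = np.clip(frame.axes[:, 0] @ [1, 0, 0], -1, 1)
            angular_errors.append(np.degrees(np.arccos(cosang)))
        assert max(angular_errors) < 0.5

    def test_parallel_long_axis_rejected(self, rng):
        fx = sample_bone_surfaces(seed=4)
        # rotate the diaphysis so its axis coincides with the condylar axis
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        bad_diaph = fx.femoral_diaphysis_points @ R.T
        with pytest.raises(ValueError, match="parallel"):
            build_femoral_frame(
                fx.condyle_points, bad_diaph, fx.landmarks["notch_apex"]
            )

    def test_coincident_plateau_centers_rejected(self):
        fx = sample_bone_surfaces(seed=5)
        p = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="coincide"):
            build_tibial_frame(
                fx.tibial_diaphysis_points,
                (p, p.copy()),
                fx.landmarks["eminence_midpoint"],
                np.zeros(3),
                proximal_hint=fx.landmarks["proximal_hint"],
            )

    def test_frames_always_orthonormal_right_handed(self):
        for seed in range(3):
            fx = sample_bone_surfaces(seed=seed, noise_sd=0.2)
            frame = build_femoral_frame(
                fx.condyle_points,
                fx.femoral_diaphysis_points,
                fx.landmarks["notch_apex"],
            )
            # BoneFrame validates orthonormality/handedness on construction
            assert isinstance(frame, BoneFrame)


class TestJointCoordinateSystem:
    def test_identical_canonical_poses_give_zeros(self):
        params = jcs_decompose(np.eye(4), np.eye(4), TF_JOINT_SPEC)
        np.testing.assert_allclose(params, np.zeros(6), atol=1e-12)

    def test_pure_parent_axis_rotation_is_flexion_only(self):
        R = Rotation.from_euler("X", 30, degrees=True).as_matrix()
        params = jcs_decompose(np.eye(4), rigid_transform(R), TF_JOINT_SPEC)
        np.testing.assert_allclose(
            params, [0, 0, 0, 30.0, 0, 0], atol=1e-10
        )

    def test_compose_of_zeros_is_identity(self):
        np.testing.assert_allclose(
            jcs_compose(np.zeros(6), TF_JOINT_SPEC), np.eye(4), atol=1e-12
        )

    def test_round_trip_many_random_poses(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(1000):
            params = random_params(rng)
            rel = jcs_compose(params, TF_JOINT_SPEC)
            back = jcs_decompose(np.eye(4), rel, TF_JOINT_SPEC)
            worst = max(worst, np.abs(back - params).max())
        assert worst < 1e-9

    @given(
        flex=st.floats(-100, 100),
        abd=st.floats(-44, 44),
        ext=st.floats(-80, 80),
        q=st.tuples(st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20)),
    )
    def test_round_trip_property(self, flex, abd, ext, q):
        params = np.array([*q, flex, abd, ext])
        back = jcs_decompose(np.eye(4), jcs_compose(params, PF_JOINT_SPEC), PF_JOINT_SPEC)
        np.testing.assert_allclose(back, params, atol=1e-9)

    def test_flexion_perturbation_isolated(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        rel0 = jcs_compose(params, TF_JOINT_SPEC)
        bumped = params.copy()
        bumped[3] += 7.0
        rel1 = jcs_compose(bumped, TF_JOINT_SPEC)
        # the relative rotation between the two poses is a pure rotation
        # about the parent fixed axis
        delta = rel0[:3, :3].T @ rel1[:3, :3]
        rotvec = Rotation.from_matrix(rel0[:3, :3] @ delta @ rel0[:3, :3].T).as_rotvec()
        np.testing.assert_allclose(
            rotvec / np.linalg.norm(rotvec), [1, 0, 0], atol=1e-9
        )

    def test_near_parallel_fixed_axes_raise(self):
        R = Rotation.from_euler("Y", -89.95, degrees=True).as_matrix()
        with pytest.raises(JointSingularityError):
            jcs_decompose(np.eye(4), rigid_transform(R), TF_JOINT_SPEC)

    def test_out_of_range_abduction_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            jcs_compose([0, 0, 0, 0, 95.0, 0], TF_JOINT_SPEC)


class TestReexpress:
    def test_identity_offsets_change_nothing(self):
        rng = np.random.default_rng(8)
        seq = np.vstack([random_params(rng) for _ in range(10)])
        out = reexpress_parameters(seq, np.eye(4), np.eye(4), TF_JOINT_SPEC)
        np.testing.assert_allclose(out, seq, atol=1e-10)

    def test_child_axis_shift_moves_one_translation_channel(self):
        rng = np.random.default_rng(9)
        seq = np.vstack([random_params(rng) for _ in range(10)])
        offset = rigid_transform(translation=(0.0, 0.0, 10.0))
        out = reexpress_parameters(seq, np.eye(4), offset, TF_JOINT_SPEC)
        np.testing.assert_allclose(out[:, 2], seq[:, 2] + 10.0, atol=1e-9)
        np.testing.assert_allclose(out[:, [0, 1, 3, 4, 5]], seq[:, [0, 1, 3, 4, 5]], atol=1e-9)

    def test_inverse_offsets_restore_original(self):
        rng = np.random.default_rng(10)
        seq = np.vstack([random_params(rng) for _ in range(5)])
        A, B = random_rigid(rng), random_rigid(rng)
        forward = reexpress_parameters(seq, A, B, TF_JOINT_SPEC)
        back = reexpress_parameters(
            forward, np.linalg.inv(A), np.linalg.inv(B), TF_JOINT_SPEC
        )
        np.testing.assert_allclose(back, seq, atol=1e-9)
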