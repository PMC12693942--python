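import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aqa.features import (
    CONTRALATERAL_PAIRS,
    FEATURE_NAMES,
    JOINT_ANGLE_TRIPLES,
    LIMB_BLOCKS,
    AccelerationSeries,
    DegenerateGeometryError,
    angle_between,
    build_features,
    compute_acceleration,
    compute_joint_angles,
    contralateral_angles,
    limb_block_center,
    limb_block_features,
    orientation_features,
)
from aqa.skeleton import KeypointSequence
from aqa.synthetic import canonical_pose, generate_template
from conftest import random_sequence


def _rotz(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestAngleBetween:
    def test_orthogonal(self):
        assert angle_between([1, 0, 0], [0, 1, 0]) == pytest.approx(np.pi / 2)

    def test_parallel_and_antiparallel(self, rng):
        v = rng.normal(size=3)
        assert angle_between(v, 2.5 * v) == pytest.approx(0.0, abs=1e-7)
        assert angle_between(v, -v) == pytest.approx(np.pi, abs=1e-7)

    def test_matches_arccos_formula(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(2, 3))
            expected = np.arccos(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))
            assert angle_between(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_between([0, 0, 0], [1, 0, 0])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_range_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=(2, 3))
        th = angle_between(a, b)
        assert 0 <= th <= np.pi
        assert angle_between(b, a) == pytest.approx(th)


class TestJointAngles:
    def test_straight_arm_reads_pi(self):
        # canonical pose has collinear shoulder-elbow-wrist segments
        theta = compute_joint_angles(canonical_pose())
        assert theta[3] == pytest.approx(np.pi)  # right elbow
        assert theta[5] == pytest.approx(np.pi)  # left elbow

    def test_right_angle_knee_reads_half_pi(self):
        pose = canonical_pose()
        pose[3] = pose[2] + np.array([0.0, 0.40, 0.0])  # shank perpendicular to thigh
        theta = compute_joint_angles(pose)
        assert theta[8] == pytest.approx(np.pi / 2)

    def test_matches_angle_between_on_triples(self, rng):
        pose = rng.normal(size=(17, 3))
        theta = compute_joint_angles(pose)
        for k, (b, a, c) in enumerate(JOINT_ANGLE_TRIPLES):
            expected = angle_between(pose[a] - pose[b], pose[c] - pose[b])
            assert theta[k] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_triple_flagged_nan(self):
        pose = canonical_pose()
        pose[15] = pose[14]  # elbow on shoulder: theta_IV undefined
        theta = compute_joint_angles(pose)
        assert np.isnan(theta[3]) and np.isfinite(np.delete(theta, 3)).all()


class TestLimbBlocks:
    def test_identical_points_center(self):
        pose = canonical_pose()
        p = np.array([1.0, 2.0, 3.0])
        pose[list(LIMB_BLOCKS["left_leg"])] = p
        np.testing.assert_allclose(limb_block_center(pose, "left_leg"), p)

    def test_center_is_coordinate_mean(self, rng):
        pose = rng.normal(size=(17, 3))
        for name, idx in LIMB_BLOCKS.items():
            np.testing.assert_allclose(
                limb_block_center(pose, name), pose[list(idx)].mean(axis=0), atol=1e-12
            )

    def test_unknown_block(self):
        with pytest.raises(KeyError):
            limb_block_center(canonical_pose(), "tail")

    def _steer_block_center(self, pose, name, target):
        # each block holds one axial keypoint (hip or thorax); move only the
        # three limb keypoints so the 4-point centre lands on `target`
        axial, *limb = LIMB_BLOCKS[name]
        pose[limb] = (4 * target - pose[axial]) / 3

    def test_center_on_spine_line_gives_zero_P(self):
        pose = canonical_pose()
        spine_dir = (pose[8] - pose[0]) / np.linalg.norm(pose[8] - pose[0])
        self._steer_block_center(pose, "left_arm", pose[0] + 0.7 * spine_dir)
        P, _ = limb_block_features(pose)
        assert P[0] == pytest.approx(0.0, abs=1e-9)

    def test_center_perpendicular_at_neck_gives_half_pi_alpha(self):
        pose = canonical_pose()
        spine = pose[8] - pose[0]
        perp = np.array([1.0, 0.0, 0.0])
        assert abs(perp @ spine) < 1e-12
        self._steer_block_center(pose, "right_arm", pose[9] + 0.5 * perp)
        _, alpha = limb_block_features(pose)
        assert alpha[1] == pytest.approx(np.pi / 2)

    def test_matches_angle_between_oracle(self, rng):
        pose = rng.normal(size=(17, 3))
        P, alpha = limb_block_features(pose)
        M = pose[8] - pose[0]
        for k, name in enumerate(("left_arm", "right_arm", "left_leg", "right_leg")):
            p0 = pose[list(LIMB_BLOCKS[name])].mean(axis=0)
            assert P[k] == pytest.approx(angle_between(M, p0 - pose[0]), abs=1e-12)
            assert alpha[k] == pytest.approx(angle_between(M, p0 - pose[9]), abs=1e-12)


class TestOrientation:
    def test_forward_facing_reads_three_half_pi(self):
        beta = orientation_features(canonical_pose())
        assert beta[0] == pytest.approx(1.5 * np.pi)
        assert beta[1] == pytest.approx(1.5 * np.pi)

    def test_reverse_facing_reads_half_pi(self):
        pose = canonical_pose() @ _rotz(np.pi).T
        beta = orientation_features(pose)
        assert beta[0] == pytest.approx(0.5 * np.pi)
        assert beta[1] == pytest.approx(0.5 * np.pi)

    def test_orientation_is_continuous_in_yaw(self):
        base = orientation_features(canonical_pose() @ _rotz(0.3).T)[0]
        assert base == pytest.approx(1.5 * np.pi - 0.3)

    @pytest.mark.parametrize("feet_factor,expected", [(0.6, 1.5), (0.4, 0.5)])
    def test_feet_opening_threshold(self, feet_factor, expected):
        pose = canonical_pose()
        w = np.linalg.norm(pose[11] - pose[14])
        pose[3] = pose[0] + np.array([+feet_factor * w / 2, 0, -0.8])
        pose[6] = pose[0] + np.array([-feet_factor * w / 2, 0, -0.8])
        assert orientation_features(pose)[2] == pytest.approx(expected * np.pi)

    def test_wrist_opening_boundary_is_strict(self):
        pose = canonical_pose()
        w = np.linalg.norm(pose[11] - pose[14])
        pose[13] = pose[9] + np.array([-0.75 * w, 0, 0])
        pose[16] = pose[9] + np.array([+0.75 * w, 0, 0])
        # separation exactly 1.5 * shoulder width: strictly-greater rule fails
        assert orientation_features(pose)[3] == pytest.approx(0.5 * np.pi)

    def test_zero_shoulder_width_raises(self):
        pose = canonical_pose()
        pose[11] = pose[14]
        with pytest.raises(DegenerateGeometryError):
            orientation_features(pose)


class TestContralateral:
    def test_parallel_segments_give_zero(self):
        pose = canonical_pose()
        d = np.array([0.3, 0.1, -0.9])
        pose[16] = pose[15] + 0.3 * d
        pose[3] = pose[2] + 0.4 * d
        assert contralateral_angles(pose)[0] == pytest.approx(0.0, abs=1e-7)

    def test_perpendicular_segments_give_half_pi(self):
        pose = canonical_pose()
        pose[13] = pose[12] + np.array([0.3, 0.0, 0.0])
        pose[6] = pose[5] + np.array([0.0, 0.4, 0.0])
        assert contralateral_angles(pose)[1] == pytest.approx(np.pi / 2)

    def test_matches_angle_between_on_pairs(self, rng):
        pose = rng.normal(size=(17, 3))
        gamma = contralateral_angles(pose)
        for k, ((a1, a2), (b1, b2)) in enumerate(CONTRALATERAL_PAIRS):
            expected = angle_between(pose[a2] - pose[a1], pose[b2] - pose[b1])
            assert gamma[k] == pytest.approx(expected, abs=1e-12)


class TestBuildFeatures:
    def test_emits_27_named_features(self, small_template):
        F = build_features(small_template)
        assert F.values.shape == (small_template.n, 27)
        assert len(FEATURE_NAMES) == 27
        assert F.names == FEATURE_NAMES
        assert np.isfinite(F.values).all()

    def test_identical_frames_give_identical_features(self):
        pose = canonical_pose()
        seq = KeypointSequence(np.repeat(pose[None], 5, axis=0), 30.0)
        F = build_features(seq).values
        assert np.ptp(F, axis=0) == pytest.approx(0.0)

    def test_translation_invariance(self, small_template):
        F1 = build_features(small_template).values
        shifted = KeypointSequence(small_template.coords + np.array([5.0, -3.0, 2.0]), 30.0)
        F2 = build_features(shifted).values
        np.testing.assert_allclose(F1, F2, atol=1e-9)

    def test_rotation_invariance_except_orientation(self, small_template):
        R = _rotz(0.7)
        rotated = KeypointSequence(small_template.coords @ R.T, 30.0)
        F1 = build_features(small_template).values
        F2 = build_features(rotated).values
        keep = [i for i, n in enumerate(FEATURE_NAMES) if n not in ("beta_1", "beta_2")]
        np.testing.assert_allclose(F1[:, keep], F2[:, keep], atol=1e-9)
        # the orientation features rotate with the body, by design
        np.testing.assert_allclose(
            np.mod(F1[:, 19] - F2[:, 19], 2 * np.pi), 0.7, atol=1e-9
        )

    def test_missing_keypoints_carry_forward(self, small_template):
        coords = small_template.coords.copy()
        coords[10, 13] = np.nan
        F_imputed = build_features(KeypointSequence(coords, 30.0))
        assert np.isfinite(F_imputed.values).all()
        with pytest.raises(ValueError, match="frame 10"):
            build_features(KeypointSequence(coords, 30.0), impute_missing=False)

    def test_missing_in_first_frame_unrecoverable(self, small_template):
        coords = small_template.coords.copy()
        coords[0, 13] = np.nan
        with pytest.raises(ValueError, match="frame 0"):
            build_features(KeypointSequence(coords, 30.0))


class TestAcceleration:
    def test_stationary_keypoint_is_zero(self):
        seq = KeypointSequence(np.zeros((10, 17, 3)), 30.0)
        np.testing.assert_array_equal(compute_acceleration(seq, 3).values, 0.0)

    def test_uniform_motion_constant_2d(self):
        coords = np.zeros((10, 17, 3))
        coords[:, 5, 0] = np.arange(10) * 0.25  # displacement d = 0.25 per frame
        seq = KeypointSequence(coords, 1.0)
        np.testing.assert_allclose(compute_acceleration(seq, 5).values, 0.5)

    def test_matches_norm_over_time_squared_oracle(self, rng):
        seq = random_sequence(rng, n=12, fps=24.0)
        acc = compute_acceleration(seq, 7)
        assert isinstance(acc, AccelerationSeries)
        assert len(acc.values) == seq.n - 2
        for i in range(seq.n - 2):
            d = np.linalg.norm(seq.coords[i + 2, 7] - seq.coords[i, 7])
            assert acc.values[i] == pytest.approx(d * 24.0**2, abs=1e-12)

    def test_invariant_under_rigid_motion(self, rng):
        seq = random_sequence(rng, n=10)
        moved = KeypointSequence(seq.coords @ _rotz(1.1).T + np.array([1, 2, 3.0]), seq.fps)
        np.testing.assert_allclose(
            compute_acceleration(moved, 4).values,
            compute_acceleration(seq, 4).values,
            atol=1e-9,
        )


def test_template_feature_values_in_expected_ranges():
    F = build_features(generate_template(80, 30, "flow", seed=3)).values
    theta_P_alpha_gamma = np.concatenate([F[:, :19], F[:, 23:]], axis=1)
    assert (theta_P_alpha_gamma >= 0).all() and (theta_P_alpha_gamma <= np.pi + 1e-12).all()
    beta12 = F[:, 19:21]
    assert (beta12 >= 0).all() and (beta12 < 2 * np.pi).all()
    assert set(np.round(F[:, 21] / np.pi, 6)) <= {0.5, 1.5}
    assert set(np.round(F[:, 22] / np.pi, 6)) <= {0.5, 1.5}
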