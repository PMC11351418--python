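import math

import numpy as np
import pytest

from liftopt import body
from liftopt import kinematics as K
from liftopt.body import (DHRow, ELBOW, GR1, GT1, GT2, HIP, KNEE, SHOULDER,
                          SPINE)


class TestDHTransform:
    def test_all_zero_row_gives_identity(self):
        row = DHRow(0.0, 0.0, 0.0, 0.0, "rotation", "global", parent=-1)
        assert np.allclose(K.dh_transform(row, 0.0), np.eye(4))

    def test_planar_link_rotation(self):
        L = 0.4
        row = DHRow(0.0, 0.0, L, 0.0, "rotation", "global", parent=-1)
        T = K.dh_transform(row, math.pi / 2)
        assert T[0, 3] == pytest.approx(L * math.cos(math.pi / 2), abs=1e-12)
        assert T[1, 3] == pytest.approx(L * math.sin(math.pi / 2), abs=1e-12)
        assert T[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert T[1, 0] == pytest.approx(1.0)

    def test_translation_row_moves_along_local_z(self):
        row = DHRow(0.0, 0.1, 0.0, 0.0, "translation", "global", parent=-1)
        T = K.dh_transform(row, 0.25)
        assert T[2, 3] == pytest.approx(0.35)
        assert np.allclose(T[:3, :3], np.eye(3))

    def test_nonfinite_coordinate_rejected(self):
        row = DHRow(0.0, 0.0, 0.0, 0.0, "rotation", "global", parent=-1)
        with pytest.raises(ValueError):
            K.dh_transform(row, np.nan)


class TestGlobalBranch:
    def test_global_rows_place_the_pelvis(self, subject):
        """Rows 1-3 at q=(z, dy, 0): pelvis at anterior z, height leg+dy."""
        q = np.zeros(10)
        q[GT1], q[GT2] = 0.3, -0.2
        leg = subject.links["L4"] + subject.links["L5"]
        pelvis = K.landmark(subject, q, "pelvis")
        assert pelvis == pytest.approx([0.0, leg - 0.2, 0.3], abs=1e-12)

    def test_pelvis_rotation_axis_is_lateral(self, subject):
        A = K.forward_kinematics(subject, np.zeros(10))
        z_axis = A[GR1][:3, 2]
        assert z_axis == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)


class TestForwardKinematics:
    def test_rotations_stay_orthonormal(self, subject, rng):
        for _ in range(200):
            q = rng.uniform(subject.q_lower, subject.q_upper)
            for A in K.forward_kinematics(subject, q):
                R = A[:3, :3]
                assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
                assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_branches_are_independent(self, subject, rng):
        q = rng.uniform(-0.5, 0.5, 10)
        q2 = q.copy()
        q2[KNEE] += 0.4          # lower-branch perturbation
        A1 = K.forward_kinematics(subject, q)
        A2 = K.forward_kinematics(subject, q2)
        for i in (SPINE, SHOULDER, ELBOW):
            assert np.allclose(A1[i], A2[i])
        assert not np.allclose(A1[body.ANKLE], A2[body.ANKLE])

    def test_wrist_height_in_standing_posture(self, subject):
        links = subject.links
        wrist = K.landmark(subject, np.zeros(10), "wrist")
        expected = (links["L4"] + links["L5"] + links["L1"]
                    - links["L2"] - links["L3"])
        assert wrist[1] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, subject):
        with pytest.raises(ValueError):
            K.forward_kinematics(subject, np.zeros(7))


class TestLandmarks:
    def test_heel_and_toe_on_ground_when_standing(self, subject):
        q = np.zeros(10)
        assert K.landmark(subject, q, "heel")[1] == pytest.approx(0.0)
        assert K.landmark(subject, q, "toe")[1] == pytest.approx(0.0)

    def test_unknown_landmark_raises(self, subject):
        with pytest.raises(ValueError, match="landmark"):
            K.landmark(subject, np.zeros(10), "elbow_pit")

    def test_hand_offset_shifts_along_forearm(self):
        m0 = body.build_human_model(1.7, 68.75)
        m1 = body.build_human_model(1.7, 68.75, hand_offset=0.07)
        q = np.zeros(10)
        d = (K.landmark(m1, q, "hand") - K.landmark(m0, q, "hand"))
        assert np.linalg.norm(d) == pytest.approx(0.07, abs=1e-12)


class TestTransformSensitivities:
    def test_matches_central_finite_differences(self, subject, rng):
        h = 1e-6
        for _ in range(20):
            q = rng.uniform(-0.8, 0.8, 10)
            S = K.transform_sensitivities(subject, q)
            j = rng.integers(0, 10)
            e = np.zeros(10)
            e[j] = h
            Ap = np.stack(K.forward_kinematics(subject, q + e))
            Am = np.stack(K.forward_kinematics(subject, q - e))
            fd = (Ap - Am) / (2 * h)
            assert np.max(np.abs(S[:, j] - fd)) < 1e-6

    def test_cross_branch_partials_vanish(self, subject, rng):
        q = rng.uniform(-0.5, 0.5, 10)
        S = K.transform_sensitivities(subject, q)
        for upper in (SPINE, SHOULDER, ELBOW):
            for lower in (HIP, KNEE, body.ANKLE, body.SUBTALAR):
                assert np.allclose(S[upper, lower], 0.0)
                assert np.allclose(S[lower, upper], 0.0)

    def test_translation_dof_sensitivity_has_zero_rotation_block(
            self, subject, rng):
        q = rng.uniform(-0.5, 0.5, 10)
        S = K.transform_sensitivities(subject, q)
        for i in range(10):
            assert np.allclose(S[i, GT1][:3, :3], 0.0)
            assert np.allclose(S[i, GT2][:3, :3], 0.0)


class TestChainDerivatives:
    def test_time_derivatives_match_finite_differences(self, subject, rng):
        q = rng.uniform(-0.6, 0.6, 10)
        qd = rng.uniform(-1, 1, 10)
        qdd = rng.uniform(-2, 2, 10)
        h = 1e-5

        def frames(t):
            return np.stack(K.forward_kinematics(
                subject, q + qd * t + 0.5 * qdd * t * t))

        A, Ad, Add = K.chain_derivatives(subject, q[None], qd[None], qdd[None])
        fd1 = (frames(h) - frames(-h)) / (2 * h)
        fd2 = (frames(h) - 2 * frames(0) + frames(-h)) / h**2
        assert np.max(np.abs(Ad[:, 0] - fd1)) < 1e-6
        assert np.max(np.abs(Add[:, 0] - fd2)) < 1e-4
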