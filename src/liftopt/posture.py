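"""Foot anchoring and synthetic squat-lift reference postures.

Foot anchoring
--------------
The two global translation DOFs are not free coordinates of the lifting
problem: the feet stay planted, so the pelvis translation is the unique
function of the rotational DOFs that keeps the ankle at the prescribed
ground point.  Because the two translations act along fixed world axes,
the elimination is exact — position, rate and acceleration of the pelvis
are recovered from a kinematic pass run with the pelvis frozen.

Reference postures
------------------
Squat-lift boundary postures (start deep squat, mid transition, end
upright) are synthesized by regularized 2D inverse kinematics: the hand
must land on the box handles exactly, a pelvis-height target shapes the
squat depth, and a posture prior keeps the solution natural and the
generator deterministic (fixed priors, no randomness).  These postures
stand in for experimentally measured joint angles in the ±epsilon posture
band of the optimization.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .body import (GR1, GT1, GT2, KNEE, N_DOF, ROTATIONAL_DOFS, HumanModel,
                   LiftingTask)
from .kinematics import chain_derivatives, chain_transforms

ROT = list(ROTATIONAL_DOFS)

# Deterministic posture priors for the eight rotational DOFs
# (pelvis pitch, spine, shoulder, elbow, hip, knee, ankle, subtalar).
# Signs: trunk flexion forward positive, arm flexion forward negative,
# squat bend hip negative / knee positive.
PRIOR_SQUAT = np.array([0.5, 1.2, -0.3, -0.3, -1.8, 2.2, -0.5, 0.0])
PRIOR_STAND = np.array([0.0, 0.05, -0.7, -0.5, -0.05, 0.05, 0.0, 0.0])


def anchor_trajectory(model: HumanModel, Q_rot, Qd_rot=None, Qdd_rot=None,
                      feet_z: float = 0.0):
    """Complete rotational trajectories into full 10-DOF trajectories with
    the pelvis translation chosen so the ankle stays at (y=0, z=feet_z).

    Q_rot etc. have shape (n_t, 8) ordered as ROTATIONAL_DOFS.  Returns
    (Q, Qd, Qdd) of shape (n_t, 10); rates/accelerations are zero-filled
    when not supplied.
    """
    Q_rot = np.atleast_2d(np.asarray(Q_rot, float))
    n_t = Q_rot.shape[0]
    Qd_rot = np.zeros_like(Q_rot) if Qd_rot is None else np.atleast_2d(Qd_rot)
    Qdd_rot = np.zeros_like(Q_rot) if Qdd_rot is None else np.atleast_2d(Qdd_rot)

    Q = np.zeros((n_t, N_DOF))
    Qd = np.zeros((n_t, N_DOF))
    Qdd = np.zeros((n_t, N_DOF))
    Q[:, ROT] = Q_rot
    Qd[:, ROT] = Qd_rot
    Qdd[:, ROT] = Qdd_rot

    # ankle motion with the pelvis frozen at the origin of its travel
    A, Ad, Add = chain_derivatives(model, Q, Qd, Qdd)
    p = A[KNEE][:, :3, 3]      # ankle = origin of the shank's distal frame
    v = Ad[KNEE][:, :3, 3]
    a = Add[KNEE][:, :3, 3]
    # GT1 translates along world z, GT2 along world y (exact superposition)
    Q[:, GT1] = feet_z - p[:, 2]
    Q[:, GT2] = -p[:, 1]
    Qd[:, GT1] = -v[:, 2]
    Qd[:, GT2] = -v[:, 1]
    Qdd[:, GT1] = -a[:, 2]
    Qdd[:, GT2] = -a[:, 1]
    return Q, Qd, Qdd


def anchored_hand(model: HumanModel, q_rot, feet_z: float = 0.0) -> np.ndarray:
    """Hand landmark position for a foot-anchored rotational posture."""
    from .body import ELBOW
    Q, _, _ = anchor_trajectory(model, np.atleast_2d(q_rot), feet_z=feet_z)
    A = chain_transforms(model, Q)
    hand = A[ELBOW][:, :3, 3] + A[ELBOW][:, :3, 0] * model.hand_offset
    return hand[0]


def anchored_pelvis_height(model: HumanModel, q_rot, feet_z: float = 0.0) -> float:
    Q, _, _ = anchor_trajectory(model, np.atleast_2d(q_rot), feet_z=feet_z)
    A = chain_transforms(model, Q)
    return A[GR1][0, 1, 3]


def _anchored_com_z(model: HumanModel, q_rot, feet_z: float) -> float:
    from .kinematics import whole_body_com
    Q, _, _ = anchor_trajectory(model, np.atleast_2d(q_rot), feet_z=feet_z)
    return whole_body_com(model, Q[0])[2]


def _solve_ik(model: HumanModel, hand_target, prior, pelvis_height_target,
              feet_z: float, hand_weight: float = 1e4,
              com_z_target: float = 0.05) -> np.ndarray:
    lo = model.q_lower[ROT]
    hi = model.q_upper[ROT]
    target = np.asarray(hand_target, float)

    from .body import ELBOW
    from .kinematics import com_local_coords
    rbar = com_local_coords(model)
    masses = np.array([model.segments[i].mass if i in model.segments else 0.0
                       for i in range(N_DOF)])
    m_tot = masses.sum()

    def residuals(q_rot):
        Q, _, _ = anchor_trajectory(model, q_rot[None, :], feet_z=feet_z)
        A = chain_transforms(model, Q)
        hand = A[ELBOW][0, :3, 3] + A[ELBOW][0, :3, 0] * model.hand_offset
        res = [hand_weight * (hand[1] - target[1]),
               hand_weight * (hand[2] - target[2])]
        if pelvis_height_target is not None:
            res.append(10.0 * (A[GR1][0, 1, 3] - pelvis_height_target))
        # keep the body CoM over the mid-foot so the boundary postures are
        # statically balanced (ZMP inside the support region)
        com_z = sum(masses[i] * (A[i, 0] @ rbar[i])[2]
                    for i in range(N_DOF) if masses[i]) / m_tot
        res.append(8.0 * (com_z - (feet_z + com_z_target)))
        res.extend(0.5 * (q_rot - prior))
        return np.asarray(res)

    sol = least_squares(residuals, np.clip(prior, lo, hi), bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    hand = anchored_hand(model, sol.x, feet_z)
    err = np.hypot(hand[1] - target[1], hand[2] - target[2])
    if err > 1e-6:
        raise ValueError(
            f"hand target {tuple(np.round(target, 3))} unreachable: residual "
            f"{err:.2e} m exceeds 1e-6 (check arm/torso reach vs target)")
    return sol.x


def reference_postures(model: HumanModel, task: LiftingTask) -> np.ndarray:
    """Per-joint reference angles at t ∈ {0, T/2, T}, shape (3, 10).

    Start: deep squat with the hands on the box at its floor position.
    End: upright stance with the hands at the delivery position.  Middle:
    hands at the midpoint, posture midway between the boundary solutions.
    All angles respect the model's joint limits (IK runs bounded) and the
    hand lands on its target to 1e-6 m.
    """
    leg = model.links["L4"] + model.links["L5"]
    q_start = _solve_ik(model, task.hand_initial, PRIOR_SQUAT,
                        pelvis_height_target=0.52 * leg,
                        feet_z=task.feet_position)
    q_end = _solve_ik(model, task.hand_final, PRIOR_STAND,
                      pelvis_height_target=0.995 * leg,
                      feet_z=task.feet_position)
    hand_mid = 0.5 * (np.asarray(task.hand_initial) + np.asarray(task.hand_final))
    q_mid = _solve_ik(model, hand_mid, 0.5 * (q_start + q_end),
                      pelvis_height_target=0.78 * leg,
                      feet_z=task.feet_position)

    out = np.zeros((3, N_DOF))
    for row, q_rot in zip(out, (q_start, q_mid, q_end)):
        Q, _, _ = anchor_trajectory(model, q_rot[None, :], feet_z=task.feet_position)
        row[:] = Q[0]
    return out


def with_reference_angles(model: HumanModel, task: LiftingTask) -> LiftingTask:
    """Return the task with synthesized reference angles filled in."""
    if task.reference_angles is not None:
        return task
    from dataclasses import replace
    return replace(task, reference_angles=reference_postures(model, task))
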