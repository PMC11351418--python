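"""Recursive DH forward kinematics for the branched 10-DOF chain.

All operators work on 4x4 homogeneous transforms.  The time-batched
variants accept trajectories (arrays with a leading time axis) and return
stacked transforms; the dynamics layer feeds on the batched first and
second time derivatives Adot, Addot computed here.

Derivatives with respect to a DOF are obtained by inserting the DH
derivative operator Q at that joint: for a rotational row
dT/dq = Q_R T and for a translational row dT/dq = Q_T T, with Q_R the
infinitesimal z-rotation generator and Q_T the z-translation generator.
"""

from __future__ import annotations

import numpy as np

from .body import (GR1, SUBTALAR, ANKLE, ELBOW, HIP, KNEE, N_DOF, SPINE,
                   HumanModel)

Z0 = np.array([0.0, 0.0, 1.0, 0.0])

Q_ROT = np.zeros((4, 4))
Q_ROT[0, 1] = -1.0
Q_ROT[1, 0] = 1.0
Q_TRANS = np.zeros((4, 4))
Q_TRANS[2, 3] = 1.0


def dh_transform(row, q_value: float) -> np.ndarray:
    """Standard DH homogeneous transform Rz(θ)·Tz(d)·Tx(a)·Rx(α) with the
    row's free coordinate (θ for rotation rows, d for translation rows)
    set to offset + q_value."""
    if not np.isfinite(q_value):
        raise ValueError("q_value must be finite")
    theta = row.theta_offset + (q_value if row.joint_kind == "rotation" else 0.0)
    d = row.d_offset + (q_value if row.joint_kind == "translation" else 0.0)
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(row.alpha), np.sin(row.alpha)
    return np.array([
        [ct, -st * ca, st * sa, row.a * ct],
        [st, ct * ca, -ct * sa, row.a * st],
        [0.0, sa, ca, d],
        [0.0, 0.0, 0.0, 1.0],
    ])


def _local_transforms(model: HumanModel, q: np.ndarray) -> np.ndarray:
    """Batched local transforms T_i: q shape (..., 10) -> (10, ..., 4, 4)."""
    q = np.asarray(q)
    if not np.iscomplexobj(q):
        q = q.astype(float)
    out = np.zeros((N_DOF,) + q.shape[:-1] + (4, 4), dtype=q.dtype)
    for i, row in enumerate(model.dh_table):
        qi = q[..., i]
        theta = row.theta_offset + (qi if row.joint_kind == "rotation" else 0.0)
        d = row.d_offset + (qi if row.joint_kind == "translation" else 0.0)
        theta = np.broadcast_to(theta, qi.shape)
        d = np.broadcast_to(d, qi.shape)
        ct, st = np.cos(theta), np.sin(theta)
        ca, sa = np.cos(row.alpha), np.sin(row.alpha)
        T = np.zeros(qi.shape + (4, 4), dtype=q.dtype)
        T[..., 0, 0] = ct
        T[..., 0, 1] = -st * ca
        T[..., 0, 2] = st * sa
        T[..., 0, 3] = row.a * ct
        T[..., 1, 0] = st
        T[..., 1, 1] = ct * ca
        T[..., 1, 2] = -ct * sa
        T[..., 1, 3] = row.a * st
        T[..., 2, 1] = sa
        T[..., 2, 2] = ca
        T[..., 2, 3] = d
        T[..., 3, 3] = 1.0
        out[i] = T
    return out


def _generator(row) -> np.ndarray:
    return Q_ROT if row.joint_kind == "rotation" else Q_TRANS


def forward_kinematics(model: HumanModel, q) -> list[np.ndarray]:
    """Global frames A_i for a single configuration q (length 10)."""
    q = np.asarray(q)
    if q.shape != (N_DOF,):
        raise ValueError(f"q must have length {N_DOF}")
    T = _local_transforms(model, q)
    A = [None] * N_DOF
    for i, row in enumerate(model.dh_table):
        A[i] = T[i] if row.parent < 0 else A[row.parent] @ T[i]
    return A


def chain_transforms(model: HumanModel, Q) -> np.ndarray:
    """Batched global frames: Q shape (n_t, 10) -> (10, n_t, 4, 4)."""
    T = _local_transforms(model, Q)
    A = np.empty_like(T)
    for i, row in enumerate(model.dh_table):
        A[i] = T[i] if row.parent < 0 else A[row.parent] @ T[i]
    return A


def chain_derivatives(model: HumanModel, Q, Qd, Qdd):
    """Batched A, Adot, Addot along a trajectory.

    Q, Qd, Qdd: (n_t, 10).  Uses the forward recursion
    Ȧ = Ȧ_p T + A_p T' q̇,  Ä = Ä_p T + 2 Ȧ_p T' q̇ + A_p (T'' q̇² + T' q̈),
    with T' = Q T (derivative-operator insertion) and T'' = Q² T.
    """
    Q = np.asarray(Q, float)
    Qd = np.asarray(Qd, float)
    Qdd = np.asarray(Qdd, float)
    T = _local_transforms(model, Q)
    A = np.empty_like(T)
    Ad = np.empty_like(T)
    Add = np.empty_like(T)
    for i, row in enumerate(model.dh_table):
        G = _generator(row)
        Ti = T[i]
        Tp = np.einsum("ab,tbc->tac", G, Ti)
        Tpp = np.einsum("ab,tbc->tac", G @ G, Ti)
        qd = Qd[:, i, None, None]
        qdd = Qdd[:, i, None, None]
        if row.parent < 0:
            A[i] = Ti
            Ad[i] = Tp * qd
            Add[i] = Tpp * qd**2 + Tp * qdd
        else:
            p = row.parent
            A[i] = A[p] @ Ti
            Ad[i] = Ad[p] @ Ti + A[p] @ Tp * qd
            Add[i] = (Add[p] @ Ti + 2.0 * (Ad[p] @ Tp) * qd
                      + A[p] @ (Tpp * qd**2 + Tp * qdd))
    return A, Ad, Add


def own_partials(model: HumanModel, Q, A=None) -> np.ndarray:
    """Batched ∂A_i/∂q_i = A_parent(i) · Q_i · T_i for every DOF."""
    T = _local_transforms(model, Q)
    if A is None:
        A = np.empty_like(T)
        for i, row in enumerate(model.dh_table):
            A[i] = T[i] if row.parent < 0 else A[row.parent] @ T[i]
    dA = np.empty_like(T)
    for i, row in enumerate(model.dh_table):
        G = _generator(row)
        GT = np.einsum("ab,tbc->tac", G, T[i])
        dA[i] = GT if row.parent < 0 else A[row.parent] @ GT
    return dA


def ancestors(model: HumanModel, i: int) -> list[int]:
    """Chain of DOF indices from the base to i (inclusive)."""
    chain = []
    while i >= 0:
        chain.append(i)
        i = model.dh_table[i].parent
    return chain[::-1]


def transform_sensitivities(model: HumanModel, q) -> np.ndarray:
    """Analytic partials ∂A_i/∂q_j for all i, j: shape (10, 10, 4, 4).

    Nonzero only when j is on i's ancestor chain: the derivative operator
    is inserted at joint j and the remaining chain multiplied through.
    """
    q = np.asarray(q, dtype=float)
    T = _local_transforms(model, q)
    A = forward_kinematics(model, q)
    out = np.zeros((N_DOF, N_DOF, 4, 4))
    for i in range(N_DOF):
        chain = ancestors(model, i)
        for j in chain:
            row_j = model.dh_table[j]
            parent = np.eye(4) if row_j.parent < 0 else A[row_j.parent]
            M = parent @ _generator(row_j) @ T[j]
            for k in chain[chain.index(j) + 1:]:
                M = M @ T[k]
            out[i, j] = M
    return out


# --- landmarks ----------------------------------------------------------

def _point(A_i: np.ndarray, local) -> np.ndarray:
    return (A_i @ np.append(np.asarray(local, float), 1.0))[:3]


def landmark(model: HumanModel, q, name: str) -> np.ndarray:
    """Global (x, y, z) of a named body point at configuration q."""
    A = forward_kinematics(model, q)
    if name == "pelvis":
        return A[GR1][:3, 3].copy()
    if name == "shoulder":
        return A[SPINE][:3, 3].copy()
    if name == "wrist":
        return A[ELBOW][:3, 3].copy()
    if name == "hand":
        return _point(A[ELBOW], [model.hand_offset, 0.0, 0.0])
    if name == "knee":
        return A[HIP][:3, 3].copy()
    if name == "ankle":
        return A[KNEE][:3, 3].copy()
    if name == "ball":
        return A[ANKLE][:3, 3].copy()
    if name == "toe_tip":
        return A[SUBTALAR][:3, 3].copy()
    if name in ("heel", "toe"):
        ankle = A[KNEE][:3, 3]
        z_heel = ankle[2] - model.heel_back
        z = z_heel if name == "heel" else z_heel + model.foot_length
        return np.array([0.0, 0.0, z])
    if name.startswith("com_"):
        dof = int(name[4:])
        seg = model.segments[dof]
        return _point(A[dof], [seg.com_offset - seg.length, 0.0, 0.0])
    raise ValueError(f"unknown landmark {name!r}")


def com_local_coords(model: HumanModel) -> np.ndarray:
    """Per-DOF segment CoM in the DOF's local frame, homogeneous (10, 4).

    The segment attached to frame i spans local x ∈ [-L, 0]; its CoM sits
    at x = com_offset - L.
    """
    out = np.zeros((N_DOF, 4))
    out[:, 3] = 1.0
    for dof, seg in model.segments.items():
        out[dof, 0] = seg.com_offset - seg.length
    return out


def hand_local_coords(model: HumanModel) -> np.ndarray:
    return np.array([model.hand_offset, 0.0, 0.0, 1.0])


def whole_body_com(model: HumanModel, q) -> np.ndarray:
    """Global CoM of the skeleton (exoskeleton masses included)."""
    A = forward_kinematics(model, q)
    num = np.zeros(3)
    m_tot = 0.0
    for dof, seg in model.segments.items():
        if seg.mass == 0.0:
            continue
        num += seg.mass * _point(A[dof], [seg.com_offset - seg.length, 0, 0])
        m_tot += seg.mass
    return num / m_tot
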