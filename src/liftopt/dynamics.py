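"""Recursive Lagrangian inverse dynamics, coupling, and GRF/ZMP.

The joint torque at DOF i is read off in a single distal-to-proximal pass:

    τ_hi = tr(∂A_i/∂q_i · D_i) − gᵀ(∂A_i/∂q_i)E_i − Σ_k f_kᵀ(∂A_i/∂q_i)F_i^k
           − G_iᵀ A_{i−1} z₀

where A_i is the global frame of DOF i, D_i the backward-recursive
inertia/Coriolis matrix (4x4, accumulating J_j Ä_jᵀ of all descendants),
E_i the backward-recursive gravity vector (accumulating m_j r̄_j), F_i^k
the backward-recursive application-point vector of external force k, and
G_i the accumulated external moments.  g is the homogeneous gravity
acceleration vector (0, −9.81, 0, 0) with world Y up.

With an exoskeleton producing τ_e at a joint, the coupled equation
τ_h + τ_e = (same right-hand side) means the human supplies the remainder.

Ground reaction forces come from a whole-body Newton–Euler balance over
segment CoM accelerations (plus the carried load); the zero-moment point
is the ground abscissa where the horizontal ground moment vanishes.  In
statics the vertical GRF is exactly total weight and the ZMP is the ground
projection of the combined CoM.  The same force/moment information is also
available from the generalized forces at the three global DOFs; the two
routes agree and that agreement is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import GR1, GT1, GT2, N_DOF, ROTATIONAL_DOFS, HumanModel
from .kinematics import (Z0, chain_derivatives, com_local_coords,
                         hand_local_coords, own_partials)


@dataclass
class ExternalLoad:
    """External forces/moments acting on the skeleton.

    forces: list of (dof, local_point, force) — world force applied at a
    point in the DOF's segment frame; local_point is (3,) when fixed in
    the segment or (n_t, 3) when it moves (e.g. the center of pressure).
    force is (n_t, 3) or (3,).
    moments: list of (dof, moment(n_t, 3) or (3,)) — world pure moments.
    """
    forces: list = field(default_factory=list)
    moments: list = field(default_factory=list)


@dataclass
class RecursionTerms:
    D: np.ndarray          # (10, n_t, 4, 4)
    E: np.ndarray          # (10, n_t, 4)
    F: list                # per external force: (10, n_t, 4)
    G: np.ndarray          # (10, n_t, 3)


@dataclass
class DynamicsResult:
    tau_h: np.ndarray      # (n_t, 10)
    grf: np.ndarray        # (n_t, 2): (horizontal F_z, vertical F_y)
    zmp: np.ndarray        # (n_t,) anterior coordinate of the ZMP
    fsr: tuple             # (heel_z, toe_z)


def pseudo_inertia(model: HumanModel) -> np.ndarray:
    """4x4 second-moment (pseudo-inertia) matrix of each segment in its
    local frame: J = [[S, m c], [m cᵀ, m]] with S the second-moment 3x3.

    Segments are thin rods along local x (S_xx,com = I_com, other
    second moments zero) with the parallel-axis shift to the frame origin.
    """
    out = np.zeros((N_DOF, 4, 4))
    for dof, seg in model.segments.items():
        c = np.array([seg.com_offset - seg.length, 0.0, 0.0])
        S = np.zeros((3, 3))
        S[0, 0] = seg.inertia
        S += seg.mass * np.outer(c, c)
        out[dof, :3, :3] = S
        out[dof, :3, 3] = seg.mass * c
        out[dof, 3, :3] = seg.mass * c
        out[dof, 3, 3] = seg.mass
    return out


def _as_time_series(arr, n_t: int, width: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = np.broadcast_to(arr, (n_t, width))
    return arr


def backward_recursion(model: HumanModel, Q, Qd, Qdd,
                       load: ExternalLoad | None = None,
                       kin=None) -> RecursionTerms:
    """Distal-to-proximal accumulation of D/E/F/G along the branched chain.

    Contributions of the upper and lower branches sum where they meet at
    the global rotation; traversal is reverse topological order.
    """
    Q = np.atleast_2d(np.asarray(Q, float))
    Qd = np.atleast_2d(np.asarray(Qd, float))
    Qdd = np.atleast_2d(np.asarray(Qdd, float))
    n_t = Q.shape[0]
    if kin is None:
        kin = chain_derivatives(model, Q, Qd, Qdd)
    A, Ad, Add = kin
    load = load or ExternalLoad()

    J = pseudo_inertia(model)
    rbar = com_local_coords(model)
    T = _locals_from_chain(model, A)

    D = np.zeros((N_DOF, n_t, 4, 4))
    E = np.zeros((N_DOF, n_t, 4))
    G = np.zeros((N_DOF, n_t, 3))
    F = [np.zeros((N_DOF, n_t, 4)) for _ in load.forces]

    children = [[] for _ in range(N_DOF)]
    for i, row in enumerate(model.dh_table):
        if row.parent >= 0:
            children[row.parent].append(i)

    for i in reversed(range(N_DOF)):
        seg_mass = model.segments[i].mass if i in model.segments else 0.0
        D[i] = np.einsum("ab,tcb->tac", J[i], Add[i])
        E[i] = seg_mass * rbar[i]
        for k, (dof, local_point, _force) in enumerate(load.forces):
            if dof == i:
                pt = np.asarray(local_point, float)
                if pt.ndim == 1:
                    F[k][i] = np.append(pt, 1.0)
                else:
                    F[k][i] = np.concatenate(
                        [pt, np.ones((n_t, 1))], axis=1)
        for dof, moment in load.moments:
            if dof == i:
                G[i] = G[i] + _as_time_series(moment, n_t, 3)
        for c in children[i]:
            D[i] = D[i] + np.einsum("tab,tbc->tac", T[c], D[c])
            E[i] = E[i] + np.einsum("tab,tb->ta", T[c], E[c])
            for k in range(len(load.forces)):
                F[k][i] = F[k][i] + np.einsum("tab,tb->ta", T[c], F[k][c])
            G[i] = G[i] + G[c]
    return RecursionTerms(D=D, E=E, F=F, G=G)


def _locals_from_chain(model: HumanModel, A: np.ndarray) -> np.ndarray:
    """Recover local transforms T_i = A_parent⁻¹ A_i from global frames."""
    T = np.empty_like(A)
    for i, row in enumerate(model.dh_table):
        if row.parent < 0:
            T[i] = A[i]
        else:
            Ap = A[row.parent]
            inv = np.empty_like(Ap)
            R = Ap[..., :3, :3]
            inv[..., :3, :3] = np.swapaxes(R, -1, -2)
            inv[..., :3, 3] = -np.einsum("tba,tb->ta", R, Ap[..., :3, 3])
            inv[..., 3, :3] = 0.0
            inv[..., 3, 3] = 1.0
            T[i] = inv @ A[i]
    return T


def inverse_dynamics(model: HumanModel, Q, Qd, Qdd,
                     load: ExternalLoad | None = None,
                     kin=None, terms: RecursionTerms | None = None) -> np.ndarray:
    """Joint torques τ_h (n_t, 10) reproducing the prescribed motion under
    gravity and the given external loads."""
    Q = np.atleast_2d(np.asarray(Q, float))
    Qd = np.atleast_2d(np.asarray(Qd, float))
    Qdd = np.atleast_2d(np.asarray(Qdd, float))
    n_t = Q.shape[0]
    load = load or ExternalLoad()
    if kin is None:
        kin = chain_derivatives(model, Q, Qd, Qdd)
    A, _, _ = kin
    if terms is None:
        terms = backward_recursion(model, Q, Qd, Qdd, load, kin=kin)
    dA = own_partials(model, Q, A=A)

    g4 = np.array([0.0, -model.gravity, 0.0, 0.0])
    tau = np.empty((n_t, N_DOF))
    for i, row in enumerate(model.dh_table):
        tau_i = np.einsum("tab,tba->t", dA[i], terms.D[i])
        tau_i -= np.einsum("a,tab,tb->t", g4, dA[i], terms.E[i])
        for k, (_dof, _pt, force) in enumerate(load.forces):
            f = _as_time_series(force, n_t, 3)
            f4 = np.concatenate([f, np.zeros((n_t, 1))], axis=1)
            tau_i -= np.einsum("ta,tab,tb->t", f4, dA[i], terms.F[k][i])
        axis = (Z0[:3] if row.parent < 0
                else np.einsum("tab,b->ta", A[row.parent][:, :3, :3], Z0[:3]))
        tau_i -= np.einsum("ta,ta->t", terms.G[i],
                           np.broadcast_to(axis, (n_t, 3)))
        tau[:, i] = tau_i
    return tau


def coupled_torques(model: HumanModel, Q, Qd, Qdd, exo_torques: dict,
                    load: ExternalLoad | None = None, kin=None) -> np.ndarray:
    """Human torques when exoskeletons supply τ_e at assisted joints:
    τ_h = (inverse dynamics) − τ_e there, unchanged elsewhere.

    exo_torques maps DOF index -> (n_t,) or scalar torque.
    """
    tau = inverse_dynamics(model, Q, Qd, Qdd, load, kin=kin)
    for dof, tau_e in exo_torques.items():
        if dof not in ROTATIONAL_DOFS:
            raise ValueError(f"exoskeleton torque at non-rotational DOF {dof}")
        tau[:, dof] = tau[:, dof] - np.asarray(tau_e, float)
    return tau


def box_load(model: HumanModel, hand_acc, box_mass: float,
             quasi_static: bool = False) -> ExternalLoad:
    """Carried-box load: a point mass rigidly held at the hand landmark.

    The hand exerts on the box m(a + g); the reaction on the human is
    f = −m·(a_hand + g_vec↑)... concretely f_y = −m(g + ÿ), f_z = −m z̈.
    quasi_static drops the inertial part (weight only).
    """
    hand_acc = np.atleast_2d(np.asarray(hand_acc, float))
    n_t = hand_acc.shape[0]
    f = np.zeros((n_t, 3))
    if quasi_static:
        f[:, 1] = -box_mass * model.gravity
    else:
        f[:, 1] = -box_mass * (model.gravity + hand_acc[:, 1])
        f[:, 2] = -box_mass * hand_acc[:, 2]
    from .body import ELBOW
    return ExternalLoad(forces=[(ELBOW, hand_local_coords(model)[:3], f)])


def ground_reaction(model: HumanModel, Q, Qd, Qdd, box_mass: float = 0.0,
                    quasi_static_box: bool = False, kin=None):
    """Whole-body Newton–Euler GRF and ZMP along a trajectory.

    Returns (grf, zmp): grf (n_t, 2) as (horizontal F_z, vertical F_y),
    zmp (n_t,) the anterior ground coordinate.  The carried box (point
    mass at the hand) is part of the supported system.  The ZMP moment
    balance includes the segments' spin angular-momentum rates about the
    lateral axis.
    """
    Q = np.atleast_2d(np.asarray(Q, float))
    Qd = np.atleast_2d(np.asarray(Qd, float))
    Qdd = np.atleast_2d(np.asarray(Qdd, float))
    n_t = Q.shape[0]
    if kin is None:
        kin = chain_derivatives(model, Q, Qd, Qdd)
    A, Ad, Add = kin
    g = model.gravity
    rbar = com_local_coords(model)

    Fy = np.zeros(n_t)
    Fz = np.zeros(n_t)
    M_heel = np.zeros(n_t)   # moment about world x at the origin
    num = np.zeros(n_t)
    points = []
    for dof, seg in model.segments.items():
        if seg.mass == 0.0:
            continue
        p = np.einsum("tab,b->ta", A[dof], rbar[dof])
        a = np.einsum("tab,b->ta", Add[dof], rbar[dof])
        points.append((seg.mass, p, a, dof))
    if box_mass > 0.0:
        from .body import ELBOW
        h = hand_local_coords(model)
        p = np.einsum("tab,b->ta", A[ELBOW], h)
        a = (np.zeros_like(p) if quasi_static_box
             else np.einsum("tab,b->ta", Add[ELBOW], h))
        points.append((box_mass, p, a, None))

    spin = _segment_spin_rate(model, A, Add)
    for m, p, a, dof in points:
        Fy += m * (a[:, 1] + g)
        Fz += m * a[:, 2]
        num += m * ((a[:, 1] + g) * p[:, 2] - a[:, 2] * p[:, 1])
    num -= spin
    zmp = num / Fy
    return np.stack([Fz, Fy], axis=1), zmp


def _segment_spin_rate(model: HumanModel, A, Add) -> np.ndarray:
    """Σ_i I_i·α_i about the lateral (world x) axis.

    The planar angular acceleration of each segment is extracted from the
    skew part of R̈ Rᵀ (α× = R̈Rᵀ − (ṘRᵀ)², whose x-component for planar
    motion sits in the (2,1)/(1,2) slots; the ω² part is symmetric and
    drops out of the skew read-off).
    """
    n_t = A.shape[1]
    out = np.zeros(n_t)
    for dof, seg in model.segments.items():
        if seg.inertia == 0.0:
            continue
        R = A[dof][:, :3, :3]
        Rdd = Add[dof][:, :3, :3]
        W = np.einsum("tab,tcb->tac", Rdd, R)   # R̈ Rᵀ
        alpha_x = 0.5 * (W[:, 2, 1] - W[:, 1, 2])
        out += seg.inertia * alpha_x
    return out


def stability_margin(zmp, fsr) -> np.ndarray:
    """Signed distance of the ZMP to the foot support region: positive
    inside, zero on the boundary, negative outside."""
    heel, toe = fsr
    if not toe > heel:
        raise ValueError("invalid foot support region")
    zmp = np.asarray(zmp, float)
    return np.minimum(zmp - heel, toe - zmp)


def contact_load(model: HumanModel, grf, zmp, A) -> ExternalLoad:
    """Ground-contact wrench as an external load on the hindfoot link.

    The GRF vector (horizontal, vertical) is applied at the zero-moment
    point on the ground — the point where the contact wrench reduces to a
    pure force — expressed in the hindfoot frame per time step.  With
    this load included, the inverse dynamics yields zero residual
    generalized force at the three global DOFs (the ground closes the
    chain) and the leg joints carry the transmitted contact wrench.
    """
    from .body import ANKLE
    grf = np.atleast_2d(np.asarray(grf, float))
    zmp = np.atleast_1d(np.asarray(zmp, float))
    n_t = grf.shape[0]
    p_world = np.zeros((n_t, 4))
    p_world[:, 2] = zmp
    p_world[:, 3] = 1.0
    Af = A[ANKLE]
    R = Af[:, :3, :3]
    local = np.einsum("tba,tb->ta", R, p_world[:, :3] - Af[:, :3, 3])
    f = np.zeros((n_t, 3))
    f[:, 1] = grf[:, 1]
    f[:, 2] = grf[:, 0]
    return ExternalLoad(forces=[(ANKLE, local, f)])


def lifting_dynamics(model: HumanModel, Q, Qd, Qdd, box_mass: float = 0.0,
                     quasi_static_box: bool = False, kin=None):
    """Full contact-consistent inverse dynamics of the lifting motion.

    Pipeline: kinematic pass → carried-box load from the hand
    acceleration → whole-body GRF and ZMP → ground wrench applied at the
    ZMP on the foot → joint torques from the recursion with both loads.

    Returns (tau, grf, zmp, load) with tau (n_t, 10).
    """
    Q = np.atleast_2d(np.asarray(Q, float))
    Qd = np.atleast_2d(np.asarray(Qd, float))
    Qdd = np.atleast_2d(np.asarray(Qdd, float))
    if kin is None:
        kin = chain_derivatives(model, Q, Qd, Qdd)
    A, Ad, Add = kin
    from .body import ELBOW
    h_local = hand_local_coords(model)
    hand_acc = np.einsum("tab,b->ta", Add[ELBOW], h_local)[:, :3]
    load = box_load(model, hand_acc, box_mass, quasi_static_box)
    grf, zmp = ground_reaction(model, Q, Qd, Qdd, box_mass=box_mass,
                               quasi_static_box=quasi_static_box, kin=kin)
    ground = contact_load(model, grf, zmp, A)
    full = ExternalLoad(forces=load.forces + ground.forces,
                        moments=load.moments + ground.moments)
    tau = inverse_dynamics(model, Q, Qd, Qdd, full, kin=kin)
    return tau, grf, zmp, full


def root_wrench(model: HumanModel, Q, Qd, Qdd,
                load: ExternalLoad | None = None, kin=None) -> np.ndarray:
    """Generalized forces at the three global DOFs from the recursion
    (n_t, 3): the net external wrench the ground must supply through the
    feet (anterior force, vertical force, sagittal moment about the
    pelvis axis).  Dual route to `ground_reaction`; used as a consistency
    check."""
    tau = inverse_dynamics(model, Q, Qd, Qdd, load, kin=kin)
    return tau[:, [GT1, GT2, GR1]]
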