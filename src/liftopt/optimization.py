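"""Inverse-dynamics trajectory optimization of the lifting task.

`LiftingOptimization` is the model object: it assembles the coupled
human–exoskeleton NLP for one lifting task — design variables are the
B-spline control points of the human joint angles and of the exoskeleton
motor currents,

    x = [P_humanᵀ  P_currentᵀ]ᵀ,

the objective is the time integral of squared normalized human joint
torques

    J(x) = Σ_i ∫₀ᵀ ( τ_hi(x) / (τ_iU − τ_iL) )² dt

over the rotational DOFs, and the constraint set covers joint angle and
torque limits, foot anchoring, hand-forward posture, collision avoidance,
ZMP stability, exoskeleton torque limits, box pick/place hand positions,
static start/end conditions, and a ±ε band around the reference postures
at t ∈ {0, T/2, T}.  `fit()` runs a sequential-quadratic-programming
solver (multi-start) and returns a `LiftingResults` object carrying the
optimal trajectories, torques, ground reactions, diagnostics and summary
table.

Joint-angle limits are imposed as bounds on the spline control points:
by the convex-hull property of B-splines, control points inside the
limits guarantee the whole trajectory is.  The zero end-velocity (static
start/end) conditions are exact linear equalities on the first/last two
control points of each clamped spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import actuator
from .body import (ELBOW, GR1, GT1, GT2, JOINT_NAMES, KNEE, N_DOF,
                   ROTATIONAL_DOFS, SPINE, ANKLE, HIP, SHOULDER,
                   HumanModel, LiftingTask, attach_exoskeletons)
from .dynamics import lifting_dynamics
from .kinematics import chain_derivatives, hand_local_coords
from .posture import anchor_trajectory, with_reference_angles
from .splines import basis_matrices

ROT = list(ROTATIONAL_DOFS)
POSTURE_BAND_DOFS = (SPINE, SHOULDER, ELBOW, HIP, KNEE, ANKLE)


def count_design_variables(n_dof: int, n_exo: int, n_ctrl: int) -> int:
    """Design-vector length n_dof·n_ctrl + n_exo·n_ctrl."""
    if n_dof <= 0 or n_ctrl <= 0 or n_exo < 0:
        raise ValueError("counts must be positive (n_exo non-negative)")
    return n_dof * n_ctrl + n_exo * n_ctrl


@dataclass
class ConstraintRow:
    """One registry entry: a named block of scalar constraints."""
    name: str
    kind: str            # "eq" | "ineq"  (ineq convention: value ≥ 0)
    index: slice         # slice into the stacked eq/ineq vector


@dataclass
class Evaluation:
    """All trajectory-level quantities at one design vector."""
    Q: np.ndarray
    Qd: np.ndarray
    Qdd: np.ndarray
    tau_id: np.ndarray       # uncoupled inverse-dynamics torques
    tau_h: np.ndarray        # human torques after exoskeleton assistance
    tau_e: np.ndarray        # (n_t, n_exo)
    currents: np.ndarray     # (n_t, n_exo)
    grf: np.ndarray
    zmp: np.ndarray
    hand: np.ndarray         # (n_t, 3)
    wrist_z: np.ndarray
    pelvis_z: np.ndarray
    objective: float
    eq: np.ndarray
    ineq: np.ndarray


class LiftingOptimization:
    """Coupled human–exoskeleton lifting model (fit with `fit()`).

    Parameters
    ----------
    human : HumanModel
        Bare subject model (exoskeleton masses are attached here).
    task : LiftingTask
        Box-lift definition; reference angles are synthesized if absent.
    exoskeletons : sequence of ExoskeletonSpec
    n_ctrl : int
        Control points per spline (default 5).
    n_t : int
        Collocation grid points on [0, T] (default 25, odd so that T/2 is
        a grid point for the posture band).
    """

    def __init__(self, human: HumanModel, task: LiftingTask, exoskeletons=(),
                 n_ctrl: int = 5, n_t: int = 25, quasi_static_box: bool = False):
        if n_t % 2 == 0:
            raise ValueError("n_t must be odd so that T/2 lies on the grid")
        self.base_human = human
        self.exos = tuple(exoskeletons)
        self.model = attach_exoskeletons(human, self.exos) if self.exos else human
        self.task = with_reference_angles(self.model, task)
        self.n_ctrl = n_ctrl
        self.n_t = n_t
        self.quasi_static_box = quasi_static_box

        T = task.duration
        self.t_grid = np.linspace(0.0, T, n_t)
        self.B0, self.B1, self.B2 = basis_matrices(n_ctrl, T, self.t_grid)
        self.w_quad = np.full(n_t, T / (n_t - 1))
        self.w_quad[[0, -1]] *= 0.5          # trapezoid weights
        self.i_mid = n_t // 2
        self.i_bounds = (0, self.i_mid, n_t - 1)

        self.n_exo = len(self.exos)
        self.n_x = count_design_variables(N_DOF, self.n_exo, n_ctrl)
        self.tau_range = (self.model.tau_upper - self.model.tau_lower)[ROT]

        self._cache_key = None
        self._cache_val = None
        self.registry: list[ConstraintRow] = []
        self._build_bounds()
        self._assemble_registry()

    @classmethod
    def from_config(cls, source, case: str = "none", **overrides
                    ) -> "LiftingOptimization":
        """Build the model from a YAML/JSON config (path, file or dict)
        and a case name selecting which exoskeletons are worn
        (none | knee | spine_shoulder | all)."""
        from .config import (build_subject, build_task, case_exoskeletons,
                             load_config)
        cfg = load_config(source)
        solver = cfg.get("solver", {}) or {}
        kw = {"n_ctrl": int(solver.get("n_ctrl", 5)),
              "n_t": int(solver.get("n_t", 25))}
        kw.update(overrides)
        return cls(build_subject(cfg), build_task(cfg),
                   exoskeletons=case_exoskeletons(cfg, case), **kw)

    # ---- design vector layout ----
    def split(self, x):
        P = np.asarray(x[: N_DOF * self.n_ctrl]).reshape(N_DOF, self.n_ctrl)
        PI = np.asarray(x[N_DOF * self.n_ctrl:]).reshape(self.n_exo, self.n_ctrl)
        return P, PI

    def _build_bounds(self):
        lo = np.empty(self.n_x)
        hi = np.empty(self.n_x)
        for i in range(N_DOF):
            s = slice(i * self.n_ctrl, (i + 1) * self.n_ctrl)
            if i in (GT1, GT2):
                lo[s] = hi[s] = 0.0   # inert: pelvis translation is anchored
            else:
                lo[s] = self.model.q_lower[i]
                hi[s] = self.model.q_upper[i]
        for k, exo in enumerate(self.exos):
            s = slice(N_DOF * self.n_ctrl + k * self.n_ctrl,
                      N_DOF * self.n_ctrl + (k + 1) * self.n_ctrl)
            lo[s] = -exo.motor.current_bound
            hi[s] = exo.motor.current_bound
        self.bounds = np.stack([lo, hi], axis=1)

    def _register(self, name, kind, n, counters):
        start = counters[kind]
        self.registry.append(ConstraintRow(name, kind, slice(start, start + n)))
        counters[kind] += n

    def _assemble_registry(self):
        """Declare the constraint blocks in evaluation order (Table-style
        registry; evaluation happens in `evaluate`)."""
        c = {"eq": 0, "ineq": 0}
        n_t, n_e = self.n_t, self.n_exo
        self._register("hand_at_box", "eq", 4, c)                # y,z at t=0,T
        self._register("static_end_rates", "eq", 2 * len(ROT), c)
        self._register("feet_contact", "eq", 2, c)               # max |ankle-target|
        self._register("torque_limits", "ineq", 2 * len(ROT) * n_t, c)
        self._register("hand_forward", "ineq", n_t, c)
        self._register("collision", "ineq",
                       len(self.model.collision_circles) * n_t, c)
        self._register("zmp_in_fsr", "ineq", 2 * n_t, c)
        if n_e:
            self._register("exo_torque_limits", "ineq", 2 * n_e * n_t, c)
        self._register("posture_band", "ineq",
                       2 * len(POSTURE_BAND_DOFS) * 3, c)
        self.n_eq = c["eq"]
        self.n_ineq = c["ineq"]

    # ---- core evaluation ----
    def evaluate(self, x) -> Evaluation:
        x = np.asarray(x, float)
        key = x.tobytes()
        if key == self._cache_key:
            return self._cache_val
        P, PI = self.split(x)
        Q_rot = self.B0 @ P[ROT].T
        Qd_rot = self.B1 @ P[ROT].T
        Qdd_rot = self.B2 @ P[ROT].T
        Q, Qd, Qdd = anchor_trajectory(self.model, Q_rot, Qd_rot, Qdd_rot,
                                       feet_z=self.task.feet_position)
        kin = chain_derivatives(self.model, Q, Qd, Qdd)
        A, Ad, Add = kin

        h_local = hand_local_coords(self.model)
        hand = np.einsum("tab,b->ta", A[ELBOW], h_local)[:, :3]
        tau_id, grf, zmp, _ = lifting_dynamics(
            self.model, Q, Qd, Qdd, box_mass=self.task.box_mass,
            quasi_static_box=self.quasi_static_box, kin=kin)

        currents = (self.B0 @ PI.T) if self.n_exo else np.zeros((self.n_t, 0))
        tau_e = np.zeros((self.n_t, self.n_exo))
        tau_h = tau_id.copy()
        for k, exo in enumerate(self.exos):
            j = exo.joint_index
            tau_e[:, k] = actuator.exo_torque(exo.motor, currents[:, k],
                                              Qd[:, j], Qdd[:, j])
            tau_h[:, j] -= tau_e[:, k]

        norm = tau_h[:, ROT] / self.tau_range
        objective = float(np.sum(self.w_quad[:, None] * norm**2))

        eq, ineq = self._constraint_values(Q, Qd, tau_h, tau_e, grf, zmp,
                                           hand, A)
        ev = Evaluation(Q=Q, Qd=Qd, Qdd=Qdd, tau_id=tau_id, tau_h=tau_h,
                        tau_e=tau_e, currents=currents, grf=grf, zmp=zmp,
                        hand=hand, wrist_z=A[ELBOW][:, 2, 3],
                        pelvis_z=A[GR1][:, 2, 3], objective=objective,
                        eq=eq, ineq=ineq)
        self._cache_key, self._cache_val = key, ev
        return ev

    def _constraint_values(self, Q, Qd, tau_h, tau_e, grf, zmp, hand, A):
        task, model = self.task, self.model
        eq = []
        # hand on the box at pick and place (meters)
        for idx, target in ((0, task.hand_initial), (-1, task.hand_final)):
            eq.extend([hand[idx, 1] - target[1], hand[idx, 2] - target[2]])
        # static start/end: joint rates vanish (rad/s; pelvis follows)
        for i in ROT:
            eq.extend([Qd[0, i], Qd[-1, i]])
        # feet anchoring (holds by construction; reported for audit)
        ankle = A[KNEE][:, :3, 3]
        eq.extend([float(np.max(np.abs(ankle[:, 1]))),
                   float(np.max(np.abs(ankle[:, 2] - task.feet_position)))])
        eq = np.asarray(eq)

        ineq = []
        # human torque limits, normalized by half the strength range
        tl = self.model.tau_lower[ROT]
        tu = self.model.tau_upper[ROT]
        half = 0.5 * self.tau_range
        ineq.append(((tu - tau_h[:, ROT]) / half).ravel())
        ineq.append(((tau_h[:, ROT] - tl) / half).ravel())
        # hand stays anterior of the pelvis
        ineq.append(A[ELBOW][:, 2, 3] - A[GR1][:, 2, 3])
        # collision: hand clear of body-thickness circles
        for circ in model.collision_circles:
            ctr = np.einsum("tab,b->ta",
                            A[circ.dof], np.append(circ.local_point, 1.0))[:, :3]
            d = np.linalg.norm(hand - ctr, axis=1)
            ineq.append(d - circ.radius)
        # ZMP inside the foot support region (normalized by foot length)
        heel = task.feet_position - model.heel_back
        toe = heel + model.foot_length
        ineq.append((zmp - heel) / model.foot_length)
        ineq.append((toe - zmp) / model.foot_length)
        # exoskeleton output torque limits
        for k, exo in enumerate(self.exos):
            ineq.append((exo.tau_limit - tau_e[:, k]) / exo.tau_limit)
            ineq.append((tau_e[:, k] + exo.tau_limit) / exo.tau_limit)
        # ±ε posture band at t = 0, T/2, T (normalized by ε)
        ref = task.reference_angles
        eps = task.epsilon
        for r, idx in enumerate(self.i_bounds):
            for i in POSTURE_BAND_DOFS:
                dq = Q[idx, i] - ref[r, i]
                ineq.append([(eps - dq) / eps, (dq + eps) / eps])
        return eq, np.concatenate([np.atleast_1d(v) for v in ineq])

    # ---- objective/constraint interfaces with shared FD Jacobians ----
    def objective(self, x) -> float:
        return self.evaluate(x).objective

    def objective_gradient(self, x) -> np.ndarray:
        """Chain-rule gradient: analytic spline basis and current terms,
        state-level central differences through the dynamics."""
        x = np.asarray(x, float)
        P, PI = self.split(x)
        ev = self.evaluate(x)
        w = self.w_quad
        resid = 2.0 * ev.tau_h[:, ROT] / self.tau_range**2       # dJ/dτ_h
        grad = np.zeros(self.n_x)

        # currents: τ_h at assisted joint = ... − GBr·K·I (affine, exact)
        for k, exo in enumerate(self.exos):
            j_rot = ROT.index(exo.joint_index)
            gain = exo.motor.gear_ratio * exo.motor.torque_constant
            rows = -(w * resid[:, j_rot] * gain) @ self.B0
            s = N_DOF * self.n_ctrl + k * self.n_ctrl
            grad[s: s + self.n_ctrl] = rows

        # rotational angle splines: FD of τ_h w.r.t. the state trajectories
        h = 1e-6
        base_args = (ev.Q[:, ROT], ev.Qd[:, ROT], ev.Qdd[:, ROT])
        basis = (self.B0, self.B1, self.B2)
        for which in range(3):
            for a in range(len(ROT)):
                args_p = [arr.copy() for arr in base_args]
                args_m = [arr.copy() for arr in base_args]
                args_p[which][:, a] += h
                args_m[which][:, a] -= h
                tp = self._tau_of_states(*args_p, ev.currents)
                tm = self._tau_of_states(*args_m, ev.currents)
                dtau = (tp - tm) / (2 * h)                        # (n_t, 8)
                sens = np.sum(resid * dtau, axis=1)               # dJ/dstate_a
                dof = ROT[a]
                s = dof * self.n_ctrl
                grad[s: s + self.n_ctrl] += (w * sens) @ basis[which]
        return grad

    def _tau_of_states(self, Q_rot, Qd_rot, Qdd_rot, currents):
        """Human torques at the rotational DOFs for given state
        trajectories (used by the gradient chain)."""
        Q, Qd, Qdd = anchor_trajectory(self.model, Q_rot, Qd_rot, Qdd_rot,
                                       feet_z=self.task.feet_position)
        tau, _, _, _ = lifting_dynamics(
            self.model, Q, Qd, Qdd, box_mass=self.task.box_mass,
            quasi_static_box=self.quasi_static_box)
        for k, exo in enumerate(self.exos):
            j = exo.joint_index
            tau[:, j] -= actuator.exo_torque(exo.motor, currents[:, k],
                                             Qd[:, j], Qdd[:, j])
        return tau[:, ROT]

    def constraints(self, x):
        ev = self.evaluate(x)
        return ev.eq, ev.ineq

    def max_violation(self, x) -> tuple[float, str]:
        """Worst normalized constraint violation and its registry name."""
        ev = self.evaluate(x)
        worst, name = 0.0, "none"
        for row in self.registry:
            vec = ev.eq[row.index] if row.kind == "eq" else ev.ineq[row.index]
            v = (np.max(np.abs(vec)) if row.kind == "eq"
                 else float(max(0.0, -np.min(vec))) if vec.size else 0.0)
            if v > worst:
                worst, name = float(v), row.name
        return worst, name

    # ---- solver ----
    def reference_start(self) -> np.ndarray:
        """Warm-start design vector: splines through the three reference
        postures with zero end rates, zero currents."""
        x = np.zeros(self.n_x)
        ref = self.task.reference_angles
        for i in ROT:
            q0, qm, qT = ref[0, i], ref[1, i], ref[2, i]
            ctrl = np.zeros(self.n_ctrl)
            ctrl[:2] = q0
            ctrl[-2:] = qT
            if self.n_ctrl > 4:
                ctrl[2: self.n_ctrl - 2] = qm
            x[i * self.n_ctrl: (i + 1) * self.n_ctrl] = ctrl
        return x

    def fit(self, starts=None, maxiter: int = 400, ftol: float = 1e-10,
            feas_tol: float = 1e-6, polish: int = 2,
            verbose: bool = False) -> "LiftingResults":
        """Solve the NLP by SQP from each start; return the best feasible
        candidate (start points themselves are candidates, so a feasible
        warm start can never be worsened)."""
        if starts is None:
            starts = [np.zeros(self.n_x), self.reference_start()]
        fd_step = 1e-7

        # the pelvis-translation control points are anchored (lb == ub):
        # optimize over the free coordinates only, and drop the
        # feet-contact audit rows (zero by construction, zero gradient)
        # from the solver's equality set.
        free = self.bounds[:, 0] != self.bounds[:, 1]
        n_solver_eq = self.n_eq - 2

        def expand(xf):
            x = np.zeros(self.n_x)
            x[free] = xf
            return x

        def jac_all(xf):
            x = expand(xf)
            ev0 = self.evaluate(x)
            f0 = np.concatenate([[ev0.objective], ev0.eq[:n_solver_eq],
                                 ev0.ineq])
            Jm = np.empty((f0.size, int(free.sum())))
            col = 0
            for i in range(self.n_x):
                if not free[i]:
                    continue
                xp = x.copy()
                xp[i] += fd_step
                evp = self.evaluate(xp)
                fp = np.concatenate([[evp.objective], evp.eq[:n_solver_eq],
                                     evp.ineq])
                Jm[:, col] = (fp - f0) / fd_step
                col += 1
            return Jm

        jac_cache = {}

        def get_jac(xf):
            key = xf.tobytes()
            if key not in jac_cache:
                jac_cache.clear()
                jac_cache[key] = jac_all(np.asarray(xf, float))
            return jac_cache[key]

        cons = [
            {"type": "eq",
             "fun": lambda xf: self.evaluate(expand(xf)).eq[:n_solver_eq],
             "jac": lambda xf: get_jac(xf)[1: 1 + n_solver_eq]},
            {"type": "ineq",
             "fun": lambda xf: self.evaluate(expand(xf)).ineq,
             "jac": lambda xf: get_jac(xf)[1 + n_solver_eq:]},
        ]

        candidates = []
        for x0 in starts:
            x0 = np.asarray(x0, float)
            candidates.append(("start", x0))
            xk = x0[free]
            for _ in range(1 + polish):
                res = minimize(lambda xf: self.objective(expand(xf)), xk,
                               jac=lambda xf: get_jac(xf)[0],
                               bounds=self.bounds[free],
                               constraints=cons, method="SLSQP",
                               options={"maxiter": maxiter, "ftol": ftol})
                xk = res.x
                candidates.append(("slsqp", expand(xk)))
                viol, _ = self.max_violation(expand(xk))
                if viol <= feas_tol:
                    break

        best = None
        for label, x in candidates:
            viol, worst = self.max_violation(x)
            obj = self.objective(x)
            feasible = viol <= feas_tol
            if verbose:
                print(f"  candidate {label}: J={obj:.6g} viol={viol:.2e} ({worst})")
            key = (not feasible, obj if feasible else viol)
            if best is None or key < best[0]:
                best = (key, x, viol, worst, feasible)
        _, x_opt, viol, worst, feasible = best
        return LiftingResults(self, x_opt, feasible=feasible,
                              max_violation=viol, worst_constraint=worst)


@dataclass
class LiftingResults:
    """Solved lifting trajectories, torques and diagnostics."""
    problem: LiftingOptimization
    x: np.ndarray
    feasible: bool
    max_violation: float
    worst_constraint: str
    _ev: Evaluation = field(default=None, repr=False)

    def __post_init__(self):
        self._ev = self.problem.evaluate(self.x)

    @property
    def status(self) -> str:
        return "success" if self.feasible else "infeasible"

    @property
    def objective(self) -> float:
        return self._ev.objective

    @property
    def t(self) -> np.ndarray:
        return self.problem.t_grid

    @property
    def tau_h(self) -> np.ndarray:
        return self._ev.tau_h

    @property
    def tau_e(self) -> np.ndarray:
        return self._ev.tau_e

    @property
    def zmp(self) -> np.ndarray:
        return self._ev.zmp

    @property
    def grf(self) -> np.ndarray:
        return self._ev.grf

    @property
    def Q(self) -> np.ndarray:
        return self._ev.Q

    def hand_error(self) -> float:
        """Worst boundary hand-position error in meters."""
        ev = self._ev
        task = self.problem.task
        errs = []
        for idx, target in ((0, task.hand_initial), (-1, task.hand_final)):
            errs.append(np.hypot(ev.hand[idx, 1] - target[1],
                                 ev.hand[idx, 2] - target[2]))
        return float(max(errs))

    def peak_torques(self) -> dict:
        """Peak |τ_h| per anatomical joint (N·m)."""
        out = {}
        for i in ROT:
            if i == GR1:
                continue
            out[JOINT_NAMES[i]] = float(np.max(np.abs(self._ev.tau_h[:, i])))
        return out

    def mechanical_energy(self, positive_work_only: bool = False) -> float:
        """Human mechanical energy ∫ Σ_i |τ_hi·q̇_i| dt over the anatomical
        joints (absolute mechanical work by default)."""
        ev = self._ev
        joints = [i for i in ROT if i != GR1]
        return work_integral(ev.tau_h[:, joints], ev.Qd[:, joints],
                             self.problem.w_quad, positive_work_only)

    def trajectory_frame(self) -> pd.DataFrame:
        """Per-grid trajectories as a tidy DataFrame (SI units)."""
        ev = self._ev
        data = {"t": self.t}
        for i in range(N_DOF):
            data[f"q_{JOINT_NAMES[i]}"] = ev.Q[:, i]
        for i in range(N_DOF):
            data[f"qd_{JOINT_NAMES[i]}"] = ev.Qd[:, i]
        for i in ROT:
            data[f"tau_{JOINT_NAMES[i]}"] = ev.tau_h[:, i]
        for k, exo in enumerate(self.problem.exos):
            nm = exo.name or JOINT_NAMES[exo.joint_index]
            data[f"tau_e_{nm}"] = ev.tau_e[:, k]
            data[f"current_{nm}"] = ev.currents[:, k]
        data["grf_z"] = ev.grf[:, 0]
        data["grf_y"] = ev.grf[:, 1]
        data["zmp"] = ev.zmp
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [
            "Lifting optimization results",
            "----------------------------",
            f"status: {self.status}   objective J = {self.objective:.6f}",
            f"max constraint violation: {self.max_violation:.3e} "
            f"({self.worst_constraint})",
            f"hand boundary error: {self.hand_error():.3e} m",
            f"mechanical energy: {self.mechanical_energy():.1f} J",
            "peak |tau_h| (N·m): " + ", ".join(
                f"{k}={v:.2f}" for k, v in self.peak_torques().items()),
        ]
        for k, exo in enumerate(self.problem.exos):
            nm = exo.name or JOINT_NAMES[exo.joint_index]
            lines.append(
                f"exo {nm}: peak |tau_e| = {np.max(np.abs(self.tau_e[:, k])):.2f} "
                f"N·m (limit {exo.tau_limit:.0f})")
        return "\n".join(lines)


def work_integral(tau, qd, weights, positive_work_only: bool = False) -> float:
    """Quadrature of summed joint mechanical power: ∫ Σ_i |τ_i·q̇_i| dt
    (or positive work only) with the given quadrature weights."""
    power = np.atleast_2d(np.asarray(tau, float) * np.asarray(qd, float))
    p = np.maximum(power, 0.0) if positive_work_only else np.abs(power)
    return float(np.sum(np.asarray(weights, float) * np.sum(p, axis=1)))


def mechanical_energy(result: LiftingResults, **kw) -> float:
    return result.mechanical_energy(**kw)


def percent_reduction(baseline: float, assisted: float) -> float:
    """100·(peak_baseline − peak_assisted)/peak_baseline."""
    if baseline == 0:
        raise ValueError("baseline peak must be nonzero")
    return 100.0 * (baseline - assisted) / baseline


def peak_torque_report(results: dict, baseline: str,
                       joints=("spine", "shoulder", "knee")) -> pd.DataFrame:
    """Per-case peak |τ_h| for the named joints and percent reductions
    relative to the baseline case."""
    if baseline not in results:
        raise ValueError(f"baseline case {baseline!r} missing")
    rows = []
    base_peaks = results[baseline].peak_torques()
    for case, res in results.items():
        peaks = res.peak_torques()
        row = {"case": case,
               "mechanical_energy_J": res.mechanical_energy()}
        for j in joints:
            row[f"peak_{j}_Nm"] = peaks[j]
            row[f"reduction_{j}_pct"] = percent_reduction(base_peaks[j], peaks[j])
        rows.append(row)
    return pd.DataFrame(rows).set_index("case")
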