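"""Inverse-dynamics checks against an independent Euler-Lagrange oracle.

The oracle never touches the backward D/E/F/G recursion: kinetic and
potential energies are assembled from forward-kinematics positions alone
(complex-step velocities, so the energies are exact to machine
precision), the mass matrix is extracted from the quadratic form, and
the Euler-Lagrange torques follow by finite differences of the
Lagrangian in time and configuration.
"""

import dataclasses

import numpy as np
import pytest

from liftopt import body
from liftopt import dynamics as D
from liftopt import kinematics as K
from liftopt.body import ELBOW, GR1, GT1, GT2, HIP, KNEE, SPINE

MASSED = [body.SPINE, body.SHOULDER, body.ELBOW, body.HIP, body.KNEE,
          body.ANKLE]


def subchain(model, keep):
    """Model with only the chosen segments massed (others zeroed)."""
    segments = dict(model.segments)
    for dof, seg in segments.items():
        if dof not in keep:
            segments[dof] = dataclasses.replace(seg, mass=0.0, inertia=0.0)
    return dataclasses.replace(model, segments=segments)


# ---- the oracle -------------------------------------------------------

def _com_states(model, q):
    rbar = K.com_local_coords(model)
    A = K.forward_kinematics(model, q)
    return A, rbar


def kinetic_energy(model, q, qd):
    """0.5 Σ m|v_com|² + 0.5 Σ I ω_x² with complex-step velocities."""
    h = 1e-200
    A_c = K.forward_kinematics(model, q + 1j * h * qd)
    A, rbar = _com_states(model, q)
    ke = 0.0
    for dof, seg in model.segments.items():
        if seg.mass == 0.0 and seg.inertia == 0.0:
            continue
        v = (A_c[dof] @ rbar[dof]).imag[:3] / h
        Rdot = A_c[dof][:3, :3].imag / h
        W = Rdot @ A[dof][:3, :3].T
        omega_x = W[2, 1]
        ke += 0.5 * seg.mass * v @ v + 0.5 * seg.inertia * omega_x**2
    return ke


def potential_energy(model, q):
    A, rbar = _com_states(model, q)
    return sum(seg.mass * model.gravity * (A[dof] @ rbar[dof])[1]
               for dof, seg in model.segments.items())


def mass_matrix(model, q):
    n = 10
    M = np.empty((n, n))
    kes = [kinetic_energy(model, q, np.eye(n)[i]) for i in range(n)]
    for i in range(n):
        M[i, i] = 2 * kes[i]
        for j in range(i + 1, n):
            ke_ij = kinetic_energy(model, q, np.eye(n)[i] + np.eye(n)[j])
            M[i, j] = M[j, i] = ke_ij - kes[i] - kes[j]
    return M


def euler_lagrange_torques(model, q, qd, qdd, hand_force=None):
    ht, hq = 1e-6, 1e-6
    Mp = mass_matrix(model, q + ht * qd)
    Mm = mass_matrix(model, q - ht * qd)
    M = mass_matrix(model, q)
    tau = M @ qdd + ((Mp - Mm) / (2 * ht)) @ qd
    for i in range(10):
        e = np.zeros(10)
        e[i] = hq
        ke_p = kinetic_energy(model, q + e, qd)
        ke_m = kinetic_energy(model, q - e, qd)
        pe_p = potential_energy(model, q + e)
        pe_m = potential_energy(model, q - e)
        tau[i] -= (ke_p - ke_m) / (2 * hq)
        tau[i] += (pe_p - pe_m) / (2 * hq)
    if hand_force is not None:
        h = 1e-200
        hand_local = K.hand_local_coords(model)
        for i in range(10):
            e = np.zeros(10)
            e[i] = h
            A_c = K.forward_kinematics(model, q + 1j * e)
            Jcol = (A_c[ELBOW] @ hand_local).imag[:3] / h
            tau[i] -= hand_force @ Jcol
    return tau


# ---- oracle-equivalence tests ----------------------------------------

def test_recursion_matches_euler_lagrange_on_random_subchains(subject, rng):
    """Eq-of-motion torques equal the energy-method torques on random
    2- and 3-link subchains, 100 random states, 1e-6 relative."""
    for trial in range(100):
        n_links = 2 + trial % 2
        keep = rng.choice(MASSED, size=n_links, replace=False)
        model = subchain(subject, set(keep.tolist()))
        q = rng.uniform(-0.8, 0.8, 10)
        qd = rng.uniform(-2, 2, 10)
        qdd = rng.uniform(-4, 4, 10)
        tau = D.inverse_dynamics(model, q, qd, qdd)[0]
        tau_el = euler_lagrange_torques(model, q, qd, qdd)
        assert np.all(np.abs(tau - tau_el) <= 1e-6 * np.maximum(
            1.0, np.abs(tau_el)))


def test_recursion_matches_oracle_with_hand_force(subject, rng):
    model = subchain(subject, {SPINE, body.SHOULDER, body.ELBOW})
    f = np.array([0.0, -98.1, 12.0])
    load = D.ExternalLoad(
        forces=[(ELBOW, K.hand_local_coords(subject)[:3], f)])
    for _ in range(10):
        q = rng.uniform(-0.8, 0.8, 10)
        qd = rng.uniform(-2, 2, 10)
        qdd = rng.uniform(-4, 4, 10)
        tau = D.inverse_dynamics(model, q, qd, qdd, load)[0]
        tau_el = euler_lagrange_torques(model, q, qd, qdd, hand_force=f)
        assert np.all(np.abs(tau - tau_el) <= 1e-6 * np.maximum(
            1.0, np.abs(tau_el)))


# ---- closed forms and structural properties ---------------------------

def test_static_pendulum_closed_form():
    """One massed link hanging from a rotational joint: static torque is
    m·g·r·sin(angle from vertical)."""
    model = body.build_human_model(1.7, 68.75)
    model = subchain(model, {HIP})        # thigh only, pivoting at the hip
    seg = model.segments[HIP]
    for phi in (0.0, 0.3, -0.7, 1.2):
        q = np.zeros(10)
        q[HIP] = phi
        tau = D.inverse_dynamics(model, q, np.zeros(10), np.zeros(10))[0]
        r = seg.com_offset
        expected = seg.mass * model.gravity * r * np.sin(phi)
        assert tau[HIP] == pytest.approx(expected, abs=1e-9)


def test_zero_mass_model_has_zero_recursion_terms(subject, rng):
    model = subchain(subject, set())
    q = rng.uniform(-1, 1, 10)
    terms = D.backward_recursion(model, q, rng.uniform(-1, 1, 10),
                                 rng.uniform(-1, 1, 10))
    assert np.allclose(terms.D, 0.0)
    assert np.allclose(terms.E, 0.0)


def test_no_external_load_means_no_force_terms(subject, rng):
    q = rng.uniform(-1, 1, 10)
    terms = D.backward_recursion(subject, q, np.zeros(10), np.zeros(10))
    assert terms.F == []
    assert np.allclose(terms.G, 0.0)


def test_zero_gravity_zero_motion_gives_zero_torque(subject):
    model = dataclasses.replace(subject, gravity=0.0)
    q = np.array([0.1, -0.05, 0.2, 0.4, -0.3, 0.2, -0.6, 1.1, -0.2, 0.05])
    tau = D.inverse_dynamics(model, q, np.zeros(10), np.zeros(10))[0]
    assert np.allclose(tau, 0.0, atol=1e-10)


class TestCoupling:
    def test_zero_exo_torque_is_identity(self, subject, rng):
        q = rng.uniform(-0.5, 0.5, 10)
        qd = rng.uniform(-1, 1, 10)
        qdd = rng.uniform(-1, 1, 10)
        tau0 = D.inverse_dynamics(subject, q, qd, qdd)
        tau = D.coupled_torques(subject, q, qd, qdd, {KNEE: 0.0})
        assert np.allclose(tau, tau0)

    def test_full_assistance_zeroes_the_joint(self, subject, rng):
        q = rng.uniform(-0.5, 0.5, 10)
        tau0 = D.inverse_dynamics(subject, q, np.zeros(10), np.zeros(10))
        tau = D.coupled_torques(subject, q, np.zeros(10), np.zeros(10),
                                {KNEE: tau0[0, KNEE]})
        assert tau[0, KNEE] == pytest.approx(0.0, abs=1e-12)

    def test_torque_sum_invariant(self, subject, rng):
        """τ_h + τ_e equals the unassisted torque at assisted joints,
        exactly, for arbitrary states and assistance levels."""
        for _ in range(20):
            q = rng.uniform(-1, 1, 10)
            qd = rng.uniform(-2, 2, 10)
            qdd = rng.uniform(-3, 3, 10)
            tau_e = {KNEE: rng.normal(), SPINE: rng.normal()}
            tau0 = D.inverse_dynamics(subject, q, qd, qdd)
            tau = D.coupled_torques(subject, q, qd, qdd, tau_e)
            for j, te in tau_e.items():
                assert tau[0, j] + te == pytest.approx(tau0[0, j], abs=1e-12)
            others = [i for i in range(10) if i not in tau_e]
            assert np.allclose(tau[0, others], tau0[0, others])

    def test_torque_at_translation_dof_rejected(self, subject):
        with pytest.raises(ValueError):
            D.coupled_torques(subject, np.zeros(10), np.zeros(10),
                              np.zeros(10), {GT1: 5.0})


class TestGroundReaction:
    def test_static_grf_is_total_weight(self, subject, rng):
        q = rng.uniform(-0.3, 0.3, 10)
        grf, _ = D.ground_reaction(subject, q, np.zeros(10), np.zeros(10))
        assert grf[0, 1] == pytest.approx(68.75 * 9.81, abs=1e-9)
        assert grf[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_static_grf_includes_carried_box(self, subject, rng):
        q = rng.uniform(-0.3, 0.3, 10)
        grf, _ = D.ground_reaction(subject, q, np.zeros(10), np.zeros(10),
                                   box_mass=10.0)
        assert grf[0, 1] == pytest.approx((68.75 + 10.0) * 9.81, abs=1e-9)

    def test_static_zmp_is_com_projection(self, subject, rng):
        q = rng.uniform(-0.3, 0.3, 10)
        _, zmp = D.ground_reaction(subject, q, np.zeros(10), np.zeros(10))
        assert zmp[0] == pytest.approx(K.whole_body_com(subject, q)[2],
                                       abs=1e-12)

    def test_dual_route_grf_agreement(self, subject, rng):
        """Newton-Euler segment sums equal the generalized forces at the
        global translation DOFs, for dynamic states."""
        q = rng.uniform(-0.5, 0.5, 10)
        qd = rng.uniform(-1, 1, 10)
        qdd = rng.uniform(-2, 2, 10)
        grf, _ = D.ground_reaction(subject, q, qd, qdd)
        wrench = D.root_wrench(subject, q, qd, qdd)
        assert wrench[0, 0] == pytest.approx(grf[0, 0], abs=1e-8)  # GT1: z
        assert wrench[0, 1] == pytest.approx(grf[0, 1], abs=1e-8)  # GT2: y

    def test_contact_load_closes_the_chain(self, subject, rng):
        """Applying the GRF at the ZMP zeroes the global residuals."""
        q = rng.uniform(-0.4, 0.4, 10)
        qd = rng.uniform(-1, 1, 10)
        qdd = rng.uniform(-1, 1, 10)
        _, _, _, full = D.lifting_dynamics(subject, q, qd, qdd, box_mass=10.0)
        resid = D.inverse_dynamics(subject, q[None], qd[None], qdd[None],
                                   full)[0, [GT1, GT2, GR1]]
        assert np.allclose(resid, 0.0, atol=1e-8)


class TestStabilityMargin:
    def test_midpoint_boundary_and_outside(self):
        fsr = (-0.08, 0.17)
        assert D.stability_margin(0.045, fsr) == pytest.approx(0.125)
        assert D.stability_margin(0.17, fsr) == pytest.approx(0.0)
        assert D.stability_margin(0.22, fsr) == pytest.approx(-0.05)

    def test_invalid_fsr_rejected(self):
        with pytest.raises(ValueError):
            D.stability_margin(0.0, (0.2, 0.1))
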