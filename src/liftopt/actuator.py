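"""DC motor electromechanics and gearbox for the powered exoskeletons.

Each device is a geared DC motor rigidly coupled to one human joint: the
rotor angle is gear_ratio times the joint angle (backlash-free).  The
motor current I(t) is a design variable (a B-spline); torque follows the
chain

    T_motor = K·I
    T_l     = T_motor − Jm·θ̈ − b·θ̇        (rotor-side load torque)
    τ_e     = GBr·T_l                       (joint-side output torque)

and the winding voltage V = L·dI/dt + K·θ̇ + R·I is available as a
feasibility diagnostic.  τ_e is affine in the current at fixed kinematics,
so its sensitivity to the current-spline control points is GBr·K times the
spline basis row.
"""

from __future__ import annotations

import numpy as np

from .body import ExoskeletonSpec, MotorSpec


def motor_torque(spec: MotorSpec, current):
    """Electromagnetic rotor torque T_motor = K·I."""
    return spec.torque_constant * np.asarray(current, float)


def rotor_kinematics(spec: MotorSpec, joint_rate, joint_accel):
    """Rotor rate and acceleration from joint kinematics through the
    rigid gearbox."""
    r = spec.gear_ratio
    return r * np.asarray(joint_rate, float), r * np.asarray(joint_accel, float)


def load_torque(spec: MotorSpec, current, rotor_rate=0.0, rotor_accel=0.0):
    """Rotor-side load torque T_l = K·I − Jm·θ̈ − b·θ̇."""
    return (motor_torque(spec, current)
            - spec.rotor_inertia * np.asarray(rotor_accel, float)
            - spec.viscous_friction * np.asarray(rotor_rate, float))


def exo_torque(spec: MotorSpec, current, joint_rate=0.0, joint_accel=0.0):
    """Joint-side output torque τ_e = GBr·T_l.

    The torque limits of the devices are optimizer constraints, not a
    saturation applied here.
    """
    rr, ra = rotor_kinematics(spec, joint_rate, joint_accel)
    return spec.gear_ratio * load_torque(spec, current, rr, ra)


def required_voltage(spec: MotorSpec, current, dI_dt=0.0, rotor_rate=0.0):
    """Winding voltage V = L·dI/dt + K·θ̇ + R·I (diagnostic)."""
    return (spec.inductance * np.asarray(dI_dt, float)
            + spec.torque_constant * np.asarray(rotor_rate, float)
            + spec.resistance * np.asarray(current, float))


def torque_current_sensitivity(spec: MotorSpec, basis_row: np.ndarray) -> np.ndarray:
    """∂τ_e/∂(current control points) = GBr·K × spline value-basis row.

    τ_e is affine in I at fixed kinematics, so the sensitivity is
    independent of the current itself and zero for other devices' control
    points.
    """
    return spec.gear_ratio * spec.torque_constant * np.asarray(basis_row, float)


def exo_torque_trajectory(exo: ExoskeletonSpec, current, joint_rate, joint_accel):
    """Output torque profile of one device along a trajectory."""
    return exo_torque(exo.motor, current, joint_rate, joint_accel)
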