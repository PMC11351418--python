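"""2D 10-DOF sagittal-plane human skeletal model.

The skeleton is a branched Denavit-Hartenberg chain rooted at the pelvis:
two global translations (pelvis anterior position and height), one global
rotation (pelvis pitch), an upper-body branch (spine, shoulder, elbow) and
a lower-body branch (hip, knee, ankle, subtalar).  The model is symmetric
about the sagittal plane; the paired arms and legs are merged into single
limbs carrying the mass, inertia and strength of both.

World frame: Y up, Z anterior, X lateral (the sagittal plane is Y-Z).  All
rotational DOFs turn about axes parallel to world X.  At the zero
configuration the model stands upright with arms hanging down and the feet
pointing anterior; the ankle sits at the world origin height y=0.

Link lengths L1..L7 (torso, upper arm, forearm, thigh, shank, hindfoot,
toes) either come from the subject directly or are derived from stature by
standard anthropometric proportions; segment masses are fixed fractions of
body mass (paired segments doubled), with slender-rod default inertias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

GRAVITY = 9.81

N_DOF = 10

# DOF indices (0-based)
GT1, GT2, GR1 = 0, 1, 2          # global: anterior translation, height, pitch
SPINE, SHOULDER, ELBOW = 3, 4, 5  # upper branch (Q1..Q3)
HIP, KNEE, ANKLE, SUBTALAR = 6, 7, 8, 9  # lower branch (Q4..Q7)

ROTATIONAL_DOFS = (GR1, SPINE, SHOULDER, ELBOW, HIP, KNEE, ANKLE, SUBTALAR)
JOINT_NAMES = {
    GT1: "gt1", GT2: "gt2", GR1: "pelvis",
    SPINE: "spine", SHOULDER: "shoulder", ELBOW: "elbow",
    HIP: "hip", KNEE: "knee", ANKLE: "ankle", SUBTALAR: "subtalar",
}
JOINT_BY_NAME = {v: k for k, v in JOINT_NAMES.items()}


@dataclass(frozen=True)
class DHRow:
    """One Denavit-Hartenberg row; the free coordinate is theta for
    rotational rows and d for translational rows (offsets add to q)."""
    theta_offset: float
    d_offset: float
    a: float
    alpha: float
    joint_kind: str          # "rotation" | "translation"
    branch: str              # "global" | "upper" | "lower"
    parent: int              # parent DOF index, -1 for the base

    def __post_init__(self):
        if self.joint_kind not in ("rotation", "translation"):
            raise ValueError(f"bad joint_kind {self.joint_kind!r}")
        if not any(math.isclose(self.alpha, v, abs_tol=1e-12)
                   for v in (0.0, math.pi / 2, -math.pi / 2)):
            raise ValueError("alpha must be 0 or ±π/2")


@dataclass(frozen=True)
class SegmentParams:
    """Rigid segment attached to a DOF's distal frame.

    com_offset is measured from the proximal end along the segment axis;
    inertia is about the segment CoM, out-of-plane axis.
    """
    length: float
    mass: float
    com_offset: float
    inertia: float

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if self.mass < 0 or self.inertia < 0:
            raise ValueError("mass and inertia must be non-negative")
        if not (0.0 <= self.com_offset <= self.length + 1e-12):
            raise ValueError("com_offset must lie within the segment")


@dataclass(frozen=True)
class MotorSpec:
    """Brushed/brushless DC motor with rigid gearbox.

    K is the torque constant (N·m/A), numerically equal in SI units to the
    back-EMF constant (V·s/rad).  The rotor spins at gear_ratio times the
    assisted joint rate.
    """
    inductance: float = 3e-4          # H
    resistance: float = 0.2           # Ω
    torque_constant: float = 0.05     # N·m/A
    rotor_inertia: float = 1e-5       # kg·m²
    viscous_friction: float = 1e-4    # N·m·s/rad
    gear_ratio: float = 80.0
    current_bound: float = 5.0        # |I| ≤ bound, A

    def __post_init__(self):
        for name in ("inductance", "resistance", "torque_constant",
                     "rotor_inertia", "viscous_friction", "current_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gear_ratio < 1:
            raise ValueError("gear_ratio must be ≥ 1")


@dataclass(frozen=True)
class ExoskeletonSpec:
    """A 1-DOF powered exoskeleton bound to one rotational human joint."""
    joint_index: int
    motor: MotorSpec
    mass: float
    tau_limit: float     # symmetric output torque bound: τ_e ∈ [-tau_limit, tau_limit]
    name: str = ""

    def __post_init__(self):
        if self.joint_index not in ROTATIONAL_DOFS:
            raise ValueError("exoskeleton must attach to a rotational DOF")
        if self.mass < 0:
            raise ValueError("exoskeleton mass must be non-negative")
        if self.tau_limit <= 0:
            raise ValueError("torque limit must be positive")

    @property
    def tau_e_lower(self) -> float:
        return -self.tau_limit

    @property
    def tau_e_upper(self) -> float:
        return self.tau_limit


# --- default device catalogue (masses and torque limits of the physical
#     knee/spine/shoulder devices; motor constants are documented defaults
#     sized so GBr·K·I_max exceeds each torque limit) ---------------------
def default_exoskeleton(joint: str) -> ExoskeletonSpec:
    catalogue = {
        "knee": dict(joint_index=KNEE, mass=2.25, tau_limit=16.0,
                     motor=MotorSpec(gear_ratio=80.0, current_bound=5.0)),
        "spine": dict(joint_index=SPINE, mass=3.4, tau_limit=36.0,
                      motor=MotorSpec(gear_ratio=100.0, current_bound=9.0)),
        "shoulder": dict(joint_index=SHOULDER, mass=1.2, tau_limit=12.0,
                         motor=MotorSpec(gear_ratio=60.0, current_bound=5.0)),
    }
    if joint not in catalogue:
        raise ValueError(f"no default exoskeleton for joint {joint!r}")
    return ExoskeletonSpec(name=joint, **catalogue[joint])


# --- anthropometry ------------------------------------------------------
# Link-length proportions of stature (Drillis–Contini style segment
# heights differenced into link lengths).
LENGTH_FRACTIONS = {
    "L1": 0.288,   # pelvis → shoulder (torso incl. head carried as mass)
    "L2": 0.186,   # upper arm
    "L3": 0.146,   # forearm (hand reference at the wrist)
    "L4": 0.245,   # thigh
    "L5": 0.246,   # shank
    "L6": 0.110,   # ankle → ball of foot
    "L7": 0.042,   # ball → toe tip
}
LINK_KEYS = tuple(LENGTH_FRACTIONS)

# Mass fractions of total body mass per model segment (paired limbs merged,
# de Leva-style values; torso carries the head, feet carry the toes).
MASS_FRACTIONS = {
    SPINE: 0.5040,     # trunk + head
    SHOULDER: 0.0542,  # both upper arms
    ELBOW: 0.0446,     # both forearms + hands
    HIP: 0.2832,       # both thighs
    KNEE: 0.0866,      # both shanks
    ANKLE: 0.0274,     # both feet
    SUBTALAR: 0.0,     # toe link (mass lumped into the foot)
}

# DOF index -> link-length key for the segment attached to that DOF
SEGMENT_LINK = {
    SPINE: "L1", SHOULDER: "L2", ELBOW: "L3",
    HIP: "L4", KNEE: "L5", ANKLE: "L6", SUBTALAR: "L7",
}

# Default joint angle bounds (rad) about the upright zero configuration and
# default joint torque bounds (N·m).  These are documented generic strength
# tables, config-overridable; the pelvis-pitch row is the ground-supplied
# sagittal moment with a wide normalization bound.
DEFAULT_Q_BOUNDS = {
    GT1: (-1.0, 1.0), GT2: (-1.0, 0.5), GR1: (-1.3, 1.3),
    SPINE: (-1.7, 1.7), SHOULDER: (-3.2, 3.2), ELBOW: (-2.7, 2.7),
    HIP: (-2.5, 2.5), KNEE: (-2.7, 2.7), ANKLE: (-1.3, 1.3),
    SUBTALAR: (-0.9, 0.9),
}
DEFAULT_TAU_BOUNDS = {
    GR1: (-500.0, 500.0),
    SPINE: (-300.0, 300.0), SHOULDER: (-120.0, 120.0), ELBOW: (-80.0, 80.0),
    HIP: (-250.0, 250.0), KNEE: (-220.0, 220.0), ANKLE: (-150.0, 150.0),
    SUBTALAR: (-60.0, 60.0),
}


@dataclass(frozen=True)
class CollisionCircle:
    """Body-thickness circle on a segment: hand-to-circle distance must stay
    at least radius."""
    dof: int          # segment frame the circle center rides on
    local_point: np.ndarray  # homogeneous-free local coords (x, y, z)
    radius: float


@dataclass(frozen=True)
class HumanModel:
    """Subject-specific 10-DOF branched skeletal model."""
    links: dict                      # L1..L7 lengths, m
    dh_table: tuple                  # 10 DHRow
    segments: dict                   # DOF -> SegmentParams
    q_lower: np.ndarray
    q_upper: np.ndarray
    tau_lower: np.ndarray            # rotational DOFs only (NaN elsewhere)
    tau_upper: np.ndarray
    collision_circles: tuple
    foot_length: float = 0.25        # heel-to-toe extent of the FSR, m
    heel_back: float = 0.08          # heel behind the ankle, m
    hand_offset: float = 0.0         # palm offset beyond the wrist, m
    gravity: float = GRAVITY
    exoskeletons: tuple = ()

    @property
    def n_dof(self) -> int:
        return N_DOF

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def subject_mass(self) -> float:
        return self.total_mass - sum(e.mass for e in self.exoskeletons)

    def segment_array(self):
        """(length, mass, com_offset, inertia) per DOF; zeros for massless
        global rows."""
        out = np.zeros((N_DOF, 4))
        for i, seg in self.segments.items():
            out[i] = (seg.length, seg.mass, seg.com_offset, seg.inertia)
        return out


def link_lengths_from_height(height: float) -> dict:
    return {k: f * height for k, f in LENGTH_FRACTIONS.items()}


def _dh_table(links: dict) -> tuple:
    L = links
    pi = math.pi
    return (
        # global branch: anterior translation, vertical translation, pitch
        DHRow(pi, 0.0, 0.0, pi / 2, "translation", "global", parent=-1),
        DHRow(pi / 2, L["L4"] + L["L5"], 0.0, -pi / 2, "translation", "global", parent=GT1),
        DHRow(0.0, 0.0, 0.0, 0.0, "rotation", "global", parent=GT2),
        # upper-body branch
        DHRow(-pi / 2, 0.0, L["L1"], 0.0, "rotation", "upper", parent=GR1),
        DHRow(pi, 0.0, L["L2"], 0.0, "rotation", "upper", parent=SPINE),
        DHRow(0.0, 0.0, L["L3"], 0.0, "rotation", "upper", parent=SHOULDER),
        # lower-body branch
        DHRow(pi / 2, 0.0, L["L4"], 0.0, "rotation", "lower", parent=GR1),
        DHRow(0.0, 0.0, L["L5"], 0.0, "rotation", "lower", parent=HIP),
        DHRow(-pi / 2, 0.0, L["L6"], 0.0, "rotation", "lower", parent=KNEE),
        DHRow(0.0, 0.0, L["L7"], 0.0, "rotation", "lower", parent=ANKLE),
    )


def build_human_model(height: float, mass: float, link_lengths: dict | None = None,
                      q_bounds: dict | None = None, tau_bounds: dict | None = None,
                      foot_length: float = 0.25, heel_back: float = 0.08,
                      hand_offset: float = 0.0) -> HumanModel:
    """Construct the subject-specific skeletal model.

    Parameters
    ----------
    height, mass : float
        Subject stature (m) and body mass (kg); both must be positive.
    link_lengths : dict, optional
        Per-link lengths L1..L7 in meters.  Absent links are derived from
        stature by the documented anthropometric proportions.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    links = link_lengths_from_height(height)
    if link_lengths:
        unknown = set(link_lengths) - set(LINK_KEYS)
        if unknown:
            raise ValueError(f"unknown link keys: {sorted(unknown)}")
        links.update(link_lengths)
    if any(v <= 0 for v in links.values()):
        raise ValueError("link lengths must be positive")

    segments = {}
    for dof, frac in MASS_FRACTIONS.items():
        length = links[SEGMENT_LINK[dof]]
        m = frac * mass
        segments[dof] = SegmentParams(
            length=length, mass=m, com_offset=0.5 * length,
            inertia=m * length**2 / 12.0)

    qb = dict(DEFAULT_Q_BOUNDS)
    if q_bounds:
        qb.update({_as_dof(k): tuple(v) for k, v in q_bounds.items()})
    tb = dict(DEFAULT_TAU_BOUNDS)
    if tau_bounds:
        tb.update({_as_dof(k): tuple(v) for k, v in tau_bounds.items()})
    q_lower = np.array([qb[i][0] for i in range(N_DOF)])
    q_upper = np.array([qb[i][1] for i in range(N_DOF)])
    tau_lower = np.full(N_DOF, np.nan)
    tau_upper = np.full(N_DOF, np.nan)
    for i in ROTATIONAL_DOFS:
        tau_lower[i], tau_upper[i] = tb[i]
    if np.any(q_lower >= q_upper):
        raise ValueError("q_lower must be < q_upper elementwise")

    circles = (
        CollisionCircle(SPINE, np.array([-0.5 * links["L1"], 0.0, 0.0]), 0.12),
        CollisionCircle(HIP, np.array([-0.5 * links["L4"], 0.0, 0.0]), 0.09),
    )
    return HumanModel(
        links=links, dh_table=_dh_table(links), segments=segments,
        q_lower=q_lower, q_upper=q_upper,
        tau_lower=tau_lower, tau_upper=tau_upper,
        collision_circles=circles, foot_length=foot_length,
        heel_back=heel_back, hand_offset=hand_offset)


def _as_dof(key) -> int:
    if isinstance(key, int):
        return key
    return JOINT_BY_NAME[key]


def attach_exoskeletons(model: HumanModel, exos) -> HumanModel:
    """Return a new model with exoskeleton masses coupled into the skeleton.

    Each device's mass is split 50/50 between the two massed segments
    flanking the assisted joint, added as point masses at the segment CoM
    (so segment CoM and CoM-inertia are unchanged and the parallel-axis
    correction is zero).  Total mass grows by exactly the device masses.
    """
    exos = tuple(exos)
    joints = [e.joint_index for e in exos]
    if len(set(joints)) != len(joints):
        raise ValueError("duplicate exoskeleton joint_index")
    # flanking massed segments for each attachable joint
    flanks = {
        KNEE: (HIP, KNEE),        # thigh, shank
        SPINE: (SPINE, HIP),      # torso, thigh (next massed segment below)
        SHOULDER: (SPINE, SHOULDER),  # torso, upper arm
        ELBOW: (SHOULDER, ELBOW),
        HIP: (SPINE, HIP),
        ANKLE: (KNEE, ANKLE),
        SUBTALAR: (ANKLE, SUBTALAR),
    }
    segments = dict(model.segments)
    for exo in exos:
        if exo.joint_index not in flanks:
            raise ValueError(f"cannot attach exoskeleton at DOF {exo.joint_index}")
        for dof in flanks[exo.joint_index]:
            seg = segments[dof]
            segments[dof] = replace(seg, mass=seg.mass + 0.5 * exo.mass)
    return replace(model, segments=segments,
                   exoskeletons=model.exoskeletons + exos)


@dataclass(frozen=True)
class LiftingTask:
    """Symmetric squat-lift of a box between two hand positions.

    Hand positions are global (x, y, z) with x lateral (always 0 in 2D),
    y vertical and z anterior.  reference_angles holds per-joint target
    angles at t ∈ {0, T/2, T} used in the ±epsilon posture band.
    """
    box_mass: float = 10.0
    box_height: float = 0.15
    box_depth: float = 0.65
    hand_initial: tuple = (0.0, 0.070, 0.418)
    hand_final: tuple = (0.0, 1.088, 0.417)
    duration: float = 1.44
    epsilon: float = 0.2          # rad, posture band half-width
    feet_position: float = 0.0    # anterior (z) ankle anchor on the ground
    reference_angles: np.ndarray | None = None   # (3, 10) once synthesized

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.box_mass < 0:
            raise ValueError("box_mass must be non-negative")
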