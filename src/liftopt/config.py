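"""YAML/JSON configuration loading and validation.

Schema (all units SI; every key optional unless noted):

subject:
  height: 1.7            # m, required
  mass: 68.75            # kg, required
  links: {L1: .., L7: ..}    # per-link lengths, m (else derived from height)
  foot_length: 0.25      # heel-to-toe support extent, m
  heel_back: 0.08        # heel behind the ankle, m
exoskeletons:            # devices available to the cases
  - joint: knee          # knee | spine | shoulder | elbow | hip | ankle
    mass: 2.25           # kg
    torque_limit: 16.0   # N·m, symmetric
    motor:               # DC motor constants (defaults if omitted)
      resistance: 0.2        # Ω
      inductance: 3.0e-4     # H
      torque_constant: 0.05  # N·m/A
      rotor_inertia: 1.0e-5  # kg·m²
      viscous_friction: 1.0e-4   # N·m·s/rad
      gear_ratio: 80.0
      current_bound: 5.0     # A
task:
  box_mass: 10.0         # kg
  box_height: 0.15       # m
  box_depth: 0.65        # m
  hand_initial: [0.0, 0.070, 0.418]   # (x, y, z) m
  hand_final: [0.0, 1.088, 0.417]
  duration: 1.44         # s
  epsilon: 0.2           # rad, posture-band half width
solver:
  n_ctrl: 5
  n_t: 25
  maxiter: 400
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .body import (JOINT_BY_NAME, ExoskeletonSpec, HumanModel, LiftingTask,
                   MotorSpec, build_human_model, default_exoskeleton)

CASES = ("none", "knee", "spine_shoulder", "all")

CASE_JOINTS = {
    "none": (),
    "knee": ("knee",),
    "spine_shoulder": ("spine", "shoulder"),
    "all": ("knee", "spine", "shoulder"),
}


class ConfigError(ValueError):
    """Configuration schema violation, reporting the offending key path."""


def _require(cfg: dict, path: str):
    node = cfg
    trail = []
    for key in path.split("."):
        trail.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config key: {'.'.join(trail)}")
        node = node[key]
    return node


def load_config(source) -> dict:
    """Load a config mapping from a YAML/JSON path, file-like or dict."""
    if isinstance(source, dict):
        return source
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    text = Path(source).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def default_config() -> dict:
    """The packaged box-lifting task: 1.70 m / 68.75 kg subject, 10 kg box
    lifted from (y, z) = (0.070, 0.418) to (1.088, 0.417) in 1.44 s."""
    return {
        "subject": {"height": 1.7, "mass": 68.75},
        "exoskeletons": [
            {"joint": "knee"}, {"joint": "spine"}, {"joint": "shoulder"},
        ],
        "task": {},
        "solver": {"n_ctrl": 5, "n_t": 25},
    }


def build_subject(cfg: dict) -> HumanModel:
    sub = _require(cfg, "subject")
    height = _require(cfg, "subject.height")
    mass = _require(cfg, "subject.mass")
    try:
        return build_human_model(
            float(height), float(mass),
            link_lengths=sub.get("links"),
            q_bounds=sub.get("q_bounds"), tau_bounds=sub.get("tau_bounds"),
            foot_length=float(sub.get("foot_length", 0.25)),
            heel_back=float(sub.get("heel_back", 0.08)),
            hand_offset=float(sub.get("hand_offset", 0.0)))
    except ValueError as exc:
        raise ConfigError(f"subject: {exc}") from exc


def build_exoskeleton(entry: dict, index: int = 0) -> ExoskeletonSpec:
    if "joint" not in entry:
        raise ConfigError(f"exoskeletons[{index}].joint is required")
    joint = entry["joint"]
    if joint not in JOINT_BY_NAME:
        raise ConfigError(
            f"exoskeletons[{index}].joint: unknown joint {joint!r} "
            f"(expected one of {sorted(JOINT_BY_NAME)})")
    try:
        base = default_exoskeleton(joint)
    except ValueError:
        base = None
    motor_kw = dict(entry.get("motor", {}))
    for flat in ("gear_ratio", "current_bound"):
        if flat in entry:
            motor_kw[flat] = entry[flat]
    try:
        if base is not None:
            motor_defaults = base.motor.__dict__ | motor_kw
            motor = MotorSpec(**motor_defaults)
            return ExoskeletonSpec(
                joint_index=JOINT_BY_NAME[joint], motor=motor,
                mass=float(entry.get("mass", base.mass)),
                tau_limit=float(entry.get("torque_limit", base.tau_limit)),
                name=joint)
        motor = MotorSpec(**motor_kw)
        return ExoskeletonSpec(
            joint_index=JOINT_BY_NAME[joint], motor=motor,
            mass=float(entry["mass"]),
            tau_limit=float(entry["torque_limit"]), name=joint)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"exoskeletons[{index}]: {exc}") from exc


def build_task(cfg: dict) -> LiftingTask:
    t = cfg.get("task", {}) or {}
    kw = {}
    for key in ("box_mass", "box_height", "box_depth", "duration", "epsilon",
                "feet_position"):
        if key in t:
            kw[key] = float(t[key])
    for key in ("hand_initial", "hand_final"):
        if key in t:
            v = t[key]
            if len(v) != 3:
                raise ConfigError(f"task.{key} must be a 3-vector (x, y, z)")
            kw[key] = tuple(float(x) for x in v)
    try:
        return LiftingTask(**kw)
    except ValueError as exc:
        raise ConfigError(f"task: {exc}") from exc


def case_exoskeletons(cfg: dict, case: str) -> list:
    if case not in CASES:
        raise ConfigError(f"unknown case {case!r}; expected one of {CASES}")
    entries = cfg.get("exoskeletons", []) or []
    specs = [build_exoskeleton(e, i) for i, e in enumerate(entries)]
    by_joint = {s.name: s for s in specs}
    out = []
    for joint in CASE_JOINTS[case]:
        out.append(by_joint.get(joint, default_exoskeleton(joint)))
    return out
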