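# Methods

This note records the model, its assumptions, the defaults that matter,
and the numerical choices, in the order a reader meets them in the code.

## Skeletal model

The skeleton is a branched DH chain of 10 DOFs in the sagittal (Y–Z)
plane, world Y up and Z anterior.  Rows 1–2 are prismatic global
translations placing the pelvis (anterior position and height above the
standing value L4+L5), row 3 the global pelvis pitch; rows 4–6 are the
upper branch (spine, shoulder, elbow, link lengths L1–L3) and rows 7–10
the lower branch (hip, knee, ankle, subtalar; L4–L7).  Both branches
chain from the global rotation.  All rotational axes are parallel to
world X.  At the zero configuration the model stands upright, arms
hanging, ankle at ground height.

Because lifting is modeled as symmetric, the paired limbs are merged:
one "arm" and one "leg" carry twice the single-limb mass and inertia.

**Anthropometry.**  Link lengths default to fixed fractions of stature
(L1 torso 0.288·H, L2 upper arm 0.186·H, L3 forearm 0.146·H, L4 thigh
0.245·H, L5 shank 0.246·H, L6 hindfoot 0.110·H, L7 toes 0.042·H), the
classical segment-height differences.  Segment masses are fixed
fractions of body mass (torso+head 0.504, arms 0.0542, forearms+hands
0.0446, thighs 0.2832, shanks 0.0866, feet 0.0274; paired values already
doubled; they sum to 1 exactly, so total model mass equals body mass
exactly).  Segments are slender rods: CoM at mid-length, I = mL²/12
about the out-of-plane axis.  These are population tables, not
subject-specific measurements — absolute torque levels therefore carry
that uncertainty, while the structural identities the tests check
(energy-oracle agreement, force balance, coupling) are exact properties
of the formulation.  Every value can be overridden in the config.

**Strength and range tables.**  Joint angle bounds and torque bounds are
generic documented defaults (e.g. spine ±300 N·m, knee ±220 N·m,
shoulder ±120 N·m; the pelvis-pitch row carries a wide ±500 N·m
normalization constant because it is the ground-supplied sagittal
moment, not a human joint — its physical realizability is exactly what
the ZMP constraint enforces).  Bounds are config-overridable; they were
chosen so the unassisted solution is interior to the torque limits.

**Exoskeleton coupling.**  A device's mass is split 50/50 onto the two
massed segments flanking its joint (knee → thigh+shank, shoulder →
torso+upper-arm, spine → torso+thigh), as point masses at the segment
CoM — so segment CoM and CoM-inertia are unchanged and total mass grows
by exactly the device mass.  Device catalogue: knee 2.25 kg / ±16 N·m,
spine 3.4 kg / ±36 N·m, shoulder 1.2 kg / ±12 N·m.

## Dynamics

Joint torques come from a recursive Lagrangian formulation on 4×4
transforms: a forward pass propagates A, Ȧ, Ä; a distal-to-proximal
pass accumulates the pseudo-inertia products D_i = J_i Ä_iᵀ + Σ T_c D_c,
gravity vectors E, external-force application vectors F and moments G;
the torque at DOF i is then read off through ∂A_i/∂q_i (the DH
derivative-operator insertion).  Gravity is g = (0, −9.81, 0, 0) m/s².

**Carried box.**  The box is a point mass rigidly held at the hand from
t = 0 to T: an external hand force (0, −m(g+ÿ_hand), −m·z̈_hand).  A
quasi-static option (weight only) exists.  Modeling the box as carried
throughout means the pick-up force transient at t = 0 is not resolved.

**Ground contact.**  The chain is pelvis-rooted, so the raw recursion
leaves a residual wrench at the three global DOFs — the wrench the
ground must supply.  The GRF is computed from the whole-body
Newton–Euler balance (Σ m(ÿ+g), Σ m z̈, box included) and the ZMP from
the moment balance including each segment's spin angular-momentum rate.
That force is applied as an external load at the ZMP on the hindfoot,
which closes the chain: the global residuals vanish identically (a
test) and the leg joints carry the transmitted contact wrench —
without this closure the knee "torque" would be only the trivial
swing-the-shank term.  Statics sanity: at rest the vertical GRF is
exactly (body+box)·g and the ZMP is the CoM ground projection.

**Foot anchoring.**  The feet stay planted, so the two pelvis
translations are not free coordinates: they are eliminated pointwise —
a kinematic pass with the pelvis frozen gives the ankle's motion, and
the pelvis position/velocity/acceleration are set so the ankle stays at
the prescribed ground point exactly for all t (the translations act
along fixed world axes, so the superposition is exact).  The
translation splines remain in the design vector for the canonical
problem-size accounting but are inert.  Enforcing the same condition as
a discretized equality on free pelvis splines would be generically
infeasible at tight tolerance (the anchored pelvis trajectory is not a
cubic spline), which is why construction was chosen over constraint.
The foot support region is [ankle−0.08 m, ankle+0.17 m] (0.25 m foot,
both feet coincident in 2D); foot-flatness between the three posture
instants is encouraged only through the ankle's posture band, not
enforced.

## Exoskeleton actuators

Rigid, backlash-free transmission: rotor angle = GBr × joint angle.
Torque chain T_motor = K·I, T_l = T_motor − J_m θ̈ − b θ̇, τ_e = GBr·T_l.
Motor defaults (R = 0.2 Ω, L = 0.3 mH, K = 0.05 N·m/A, J_m = 1e-5 kg·m²,
b = 1e-4 N·m·s/rad) are typical for geared exoskeleton drives; gear
ratios (80/100/60) and current bounds (5/9/5 A) are sized so
GBr·K·I_max exceeds each device's torque limit.  The winding voltage is
a diagnostic, not a constraint (switchable).  τ_e is affine in current
at fixed kinematics, so current sensitivities are exact (GBr·K × basis
row).

## Reference postures

The ±0.2 rad posture band needs target angles at t ∈ {0, T/2, T}.  They
are synthesized deterministically (no randomness anywhere in the
package) by bounded regularized IK: the hand must land on the box
handles to 1e-6 m; a pelvis-height target sets squat depth (0.52, 0.78,
0.995 × leg length at start/mid/end); a CoM-over-midfoot residual keeps
each posture statically balanced; fixed priors keep the solution in the
natural squat-lift basin (trunk flexion forward positive, arm flexion
negative, hip−/knee+ bend).  Whether the 0.2 band half-width is radians
is an assumption (flagged; configurable via the task's `epsilon`).

These postures emulate what a motion-capture session would provide.
They reproduce the qualitative squat-lift strategy but not any specific
subject's style, so solved absolute peak torques are indicative, not
subject-matched; the comparative quantities (reductions, monotonicity,
limit saturation) are the meaningful outputs.

## The NLP

Design vector: 5-control-point clamped cubic B-splines per DOF and per
device current (50–65 variables).  Collocation grid: 25 uniform points
(odd, so T/2 is on the grid); objective and energy use trapezoid
quadrature (a 10× finer grid moves the objective by <1%, a test).
Constraints per grid point: torque limits (normalized by half the
strength range), hand anterior of pelvis, hand clear of two
body-thickness circles (torso r = 0.12 m, thigh r = 0.09 m), ZMP inside
the support region (normalized by foot length), device torque limits
(normalized by the limit); at the three posture instants the ±ε band
for spine, shoulder, elbow, hip, knee, ankle; equalities: hand on the
box at t = 0 and T (meters), zero end rates as exact linear equalities
on the first/last two control points of each clamped spline.
Joint-angle limits are bounds on control points — by the convex-hull
property the whole trajectory then respects them, with no per-grid
rows.  Constraint counts therefore differ from any fixed reference
count; the registry is introspectable.

Solver: scipy's SLSQP with a shared forward-difference Jacobian over
the free design coordinates (step 1e-7), multi-start from x₀ = 0 and
from a reference-posture warm start (control points [q₀,q₀,q_mid,q_T,q_T],
zero currents).  Start points are themselves candidates, and the best
*feasible* candidate (violation ≤ 1e-6 in normalized units) with the
lowest objective is returned — so a feasible warm start can never be
worsened, which is also what makes assistance by an idealized massless,
frictionless device provably non-harmful (zero current embeds the
unassisted optimum).  The objective also has a chain-rule gradient
(analytic spline basis and current terms, state-level central
differences through the dynamics) used for gradient verification.

Both default starts converge to the same optimum on the packaged task;
the solutions reported by `scripts/acceptance.py` are feasible to ~1e-11.

Grid and spline sizes (n_t = 25, n_ctrl = 5) keep a full case solve in
the tens of seconds on one CPU; coarser grids (n_t = 9) are used for
structural tests.

**Mechanical energy** is ∫ Σ_i |τ_hi q̇_i| dt over the seven anatomical
joints (absolute mechanical work; a positive-work-only variant is a
flag).  The pelvis-pitch row is excluded — its power is delivered by
the ground, not by muscles.

## Torque–angle controller

The knee device's optimal τ*(t) is refit as a single-valued cubic
B-spline in the encoder angle over the motion's range, least squares on
the time-aligned samples, control points clamped to the device limit
(convex hull ⇒ the whole map respects it).  Default 8 control points:
the assistive torque reverses sharply near full knee extension and
needs finer angle resolution than the time-domain splines.  Down-phase/
up-phase hysteresis is averaged by the single-valued fit.  Out-of-range
lookups hold the boundary torque (safe-torque choice; zero-torque mode
available).

## Known limitations

* Sagittal-plane symmetric lifting only; no 3D/asymmetric tasks.
* No foot rollover, flight phases, or friction-cone contact modeling;
  the feet share one coincident support region.
* Population anthropometry and generic strength tables stand in for
  subject-specific measurements, so absolute torque magnitudes are
  approximate; comparative metrics are the robust outputs.
* The SQP finds local optima; the two packaged starts agree on the
  shipped task, but unusual tasks may need more starts.
* The box-force transient at pick-up is not modeled (box carried from
  t = 0).
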