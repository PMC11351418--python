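"""Torque-vs-angle exoskeleton controller fitting.

The optimizer produces the optimal assistive torque as a function of
time; a wearable controller needs it as a function of the joint encoder
angle.  `fit_control_map` least-squares fits a cubic B-spline τ(θ) over
the motion's angle range to the time-aligned (θ(t), τ*(t)) samples and
clamps the control points to the device torque limit (by the convex-hull
property the whole map then respects the limit).  Ascending/descending
phase hysteresis is averaged into the single-valued fit.  Out-of-domain
lookups hold the boundary value by default (safe-torque rationale) or
return zero torque when configured so.
"""

from __future__ import annotations

from dataclasses import dataclass

import json

import numpy as np

from .splines import CubicBSplineTrajectory, fit_least_squares


@dataclass
class TorqueAngleMap:
    """Continuous torque lookup over a joint-angle domain."""
    spline: CubicBSplineTrajectory
    theta_min: float
    theta_max: float
    limit: float
    out_of_domain: str = "hold"      # "hold" | "zero"

    def lookup(self, theta):
        theta = np.asarray(theta, float)
        inside = (theta >= self.theta_min) & (theta <= self.theta_max)
        clipped = np.clip(theta, self.theta_min, self.theta_max)
        val, _, _ = self.spline.evaluate(clipped - self.theta_min)
        if self.out_of_domain == "zero":
            val = np.where(inside, val, 0.0)
        return val if val.shape else float(val)

    __call__ = lookup

    def max_abs_torque(self, n: int = 512) -> float:
        theta = np.linspace(self.theta_min, self.theta_max, n)
        return float(np.max(np.abs(self.lookup(theta))))

    def export_table(self, path, n: int = 200):
        """CSV lookup table (theta_rad, torque_Nm)."""
        theta = np.linspace(self.theta_min, self.theta_max, n)
        tau = self.lookup(theta)
        arr = np.stack([theta, tau], axis=1)
        np.savetxt(path, arr, delimiter=",", header="theta_rad,torque_Nm",
                   comments="")

    def export_coefficients(self, path):
        payload = {
            "degree": self.spline.degree,
            "knots": (self.spline.knots + self.theta_min).tolist(),
            "control_points": self.spline.control_points.tolist(),
            "theta_min": self.theta_min,
            "theta_max": self.theta_max,
            "limit": self.limit,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_control_map(tau_opt, theta_opt, n_ctrl: int = 8, limit: float = 16.0,
                    out_of_domain: str = "hold") -> TorqueAngleMap:
    """Fit the torque-angle controller from time-aligned samples.

    Parameters
    ----------
    tau_opt, theta_opt : arrays of equal length
        Optimal assistive torque τ*(t_k) and joint angle θ(t_k) samples.
    n_ctrl : int
        Control points of the τ(θ) spline (default 8: the assistive
        torque varies sharply near full knee extension and needs finer
        angle resolution than the time-domain trajectories).
    limit : float
        Device torque bound; control points are clamped to ±limit after
        the fit so max |τ(θ)| ≤ limit exactly.
    """
    tau_opt = np.asarray(tau_opt, float)
    theta_opt = np.asarray(theta_opt, float)
    if tau_opt.shape != theta_opt.shape:
        raise ValueError("samples must be time-aligned (equal length)")
    tmin, tmax = float(np.min(theta_opt)), float(np.max(theta_opt))
    if tmax - tmin < 1e-9:
        raise ValueError("degenerate angle domain: θ(t) is constant")
    spline = fit_least_squares(np.stack([theta_opt, tau_opt], axis=1),
                               n_ctrl, (tmin, tmax))
    spline.control_points[:] = np.clip(spline.control_points, -limit, limit)
    spline = CubicBSplineTrajectory(spline.control_points, tmax - tmin)
    return TorqueAngleMap(spline, tmin, tmax, limit, out_of_domain)


def fit_residual_rms(mapping: TorqueAngleMap, tau_opt, theta_opt) -> float:
    """RMS of τ*(t) − map(θ(t)) over the fitted samples."""
    pred = mapping.lookup(np.asarray(theta_opt, float))
    return float(np.sqrt(np.mean((np.asarray(tau_opt, float) - pred) ** 2)))
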