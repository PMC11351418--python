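"""Clamped cubic B-spline trajectories.

Joint-angle profiles q(t) and exoskeleton motor-current profiles I(t) are
parameterized as clamped cubic B-splines over the lifting interval [0, T];
the spline control points are the design variables of the trajectory
optimization.  Because spline evaluation is linear in the control points,
the basis rows returned by :meth:`CubicBSplineTrajectory.basis` double as
exact sensitivities for gradient-based solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def clamped_knots(n_ctrl: int, duration: float, degree: int = 3) -> np.ndarray:
    """Clamped knot vector over [0, duration] with uniform interior knots."""
    if n_ctrl < degree + 1:
        raise ValueError(f"need at least {degree + 1} control points, got {n_ctrl}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_interior = n_ctrl - degree - 1
    interior = np.linspace(0.0, duration, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.zeros(degree + 1), interior, np.full(degree + 1, duration)]
    )


@dataclass
class CubicBSplineTrajectory:
    """A scalar clamped cubic B-spline trajectory on [0, duration].

    Parameters
    ----------
    control_points : (n_ctrl,) array
        Spline coefficients; with a clamped knot vector the curve
        interpolates the first and last control point at t=0 and t=T.
    duration : float
        Total trajectory time T in seconds.
    """

    control_points: np.ndarray
    duration: float
    degree: int = 3
    knots: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.knots is None:
            self.knots = clamped_knots(len(self.control_points), self.duration, self.degree)
        self._spline = BSpline(self.knots, self.control_points, self.degree)
        self._d1 = self._spline.derivative(1)
        self._d2 = self._spline.derivative(2)

    @property
    def n_ctrl(self) -> int:
        return len(self.control_points)

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.duration + 1e-12):
            raise ValueError(f"t outside [0, {self.duration}]")
        return np.clip(t, 0.0, self.duration)

    def evaluate(self, t):
        """Return (value, rate, acceleration) at time(s) t."""
        t = self._check_domain(t)
        return self._spline(t), self._d1(t), self._d2(t)

    def basis(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Basis rows (B0, B1, B2): value/rate/acceleration as linear maps.

        Each row r satisfies value(t) = r @ control_points (resp. rate,
        acceleration), i.e. these are the exact sensitivities of the
        evaluated trajectory with respect to the control points.
        """
        return basis_matrices(self.n_ctrl, self.duration, t, self.degree)

    # alias matching the optimizer-facing vocabulary
    basis_sensitivity = basis


def basis_matrices(n_ctrl: int, duration: float, t, degree: int = 3):
    """Design matrices (B0, B1, B2) of shape (len(t), n_ctrl).

    B0 @ P gives values at t, B1 @ P rates, B2 @ P accelerations, for any
    control-point vector P on the clamped uniform knot vector.
    """
    knots = clamped_knots(n_ctrl, duration, degree)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < -1e-12) or np.any(t > duration + 1e-12):
        raise ValueError(f"t outside [0, {duration}]")
    t = np.clip(t, 0.0, duration)
    ident = BSpline(knots, np.eye(n_ctrl), degree)
    return ident(t), ident.derivative(1)(t), ident.derivative(2)(t)


def endpoint_rate_rows(n_ctrl: int, duration: float, degree: int = 3):
    """Rate basis rows at t=0 and t=T.

    For a clamped spline the end rates depend only on the first (last) two
    control points, so zero end-velocity boundary conditions reduce to
    linear equalities on the design vector.
    """
    _, b1, _ = basis_matrices(n_ctrl, duration, [0.0, duration], degree)
    return b1[0], b1[1]


def fit_least_squares(samples, n_ctrl: int, domain: tuple[float, float],
                      degree: int = 3) -> CubicBSplineTrajectory:
    """Least-squares clamped cubic B-spline through (abscissa, value) samples.

    The abscissae must span the domain well enough that the design matrix
    has full column rank (every basis function observed); otherwise the fit
    is declared degenerate.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (abscissa, value)")
    if len(samples) < n_ctrl:
        raise ValueError(f"need at least n_ctrl={n_ctrl} samples, got {len(samples)}")
    lo, hi = domain
    if not hi > lo:
        raise ValueError("degenerate domain")
    x = samples[:, 0] - lo
    y = samples[:, 1]
    span = hi - lo
    b0, _, _ = basis_matrices(n_ctrl, span, np.clip(x, 0.0, span), degree)
    if np.linalg.matrix_rank(b0) < n_ctrl:
        raise ValueError("rank-deficient design: samples do not span the domain")
    coef, *_ = np.linalg.lstsq(b0, y, rcond=None)
    return CubicBSplineTrajectory(coef, span, degree)
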