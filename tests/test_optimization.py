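import numpy as np
import pytest

from liftopt import body
from liftopt import optimization as O
from liftopt.body import default_exoskeleton


@pytest.fixture(scope="module")
def small_problem(subject, task):
    """A coarse-grid instance used for structural and gradient checks."""
    return O.LiftingOptimization(subject, task, n_t=9)


@pytest.fixture(scope="module")
def small_knee_problem(subject, task):
    return O.LiftingOptimization(subject, task,
                                 exoskeletons=[default_exoskeleton("knee")],
                                 n_t=9)


class TestDesignVariableCounts:
    @pytest.mark.parametrize("n_exo,expected",
                             [(0, 50), (1, 55), (2, 60), (3, 65)])
    def test_cases_match_formula(self, n_exo, expected):
        assert O.count_design_variables(10, n_exo, 5) == expected

    def test_problem_vector_length(self, small_problem, small_knee_problem):
        assert small_problem.n_x == 50
        assert small_knee_problem.n_x == 55

    def test_three_exo_problem_has_65_variables(self, subject, task):
        exos = [default_exoskeleton(j) for j in ("knee", "spine", "shoulder")]
        p = O.LiftingOptimization(subject, task, exoskeletons=exos, n_t=9)
        assert p.n_x == 65

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            O.count_design_variables(0, 1, 5)


class TestObjective:
    def test_scales_inversely_with_squared_torque_range(self, small_problem):
        x = small_problem.reference_start()
        j1 = small_problem.objective(x)
        small_problem.tau_range = small_problem.tau_range / 2.0
        try:
            small_problem._cache_key = None
            j2 = small_problem.objective(x)
        finally:
            small_problem.tau_range = small_problem.tau_range * 2.0
            small_problem._cache_key = None
        assert j2 == pytest.approx(4 * j1, rel=1e-12)

    def test_quadrature_converges_under_grid_refinement(self, subject, task):
        coarse = O.LiftingOptimization(subject, task, n_t=25)
        fine = O.LiftingOptimization(subject, task, n_t=249)
        x = coarse.reference_start()
        assert fine.objective(x) == pytest.approx(coarse.objective(x),
                                                  rel=0.01)

    def test_gradient_matches_finite_differences(self, small_knee_problem,
                                                 rng):
        """Chain-rule objective gradient vs brute-force design-vector FD."""
        p = small_knee_problem
        x = p.reference_start()
        x += 0.02 * rng.standard_normal(p.n_x)
        x[body.GT1 * 5: (body.GT2 + 1) * 5] = 0.0   # anchored entries
        g = p.objective_gradient(x)
        h = 1e-6
        idx = [15, 22, 33, 41, 50, 52, 54]           # angles and currents
        for i in idx:
            e = np.zeros(p.n_x)
            e[i] = h
            fd = (p.objective(x + e) - p.objective(x - e)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestConstraintRegistry:
    def test_no_exo_registry_has_no_exo_rows(self, small_problem):
        names = [r.name for r in small_problem.registry]
        assert "exo_torque_limits" not in names
        for expected in ("hand_at_box", "static_end_rates", "torque_limits",
                         "hand_forward", "collision", "zmp_in_fsr",
                         "posture_band", "feet_contact"):
            assert names.count(expected) == 1

    def test_exo_problem_gains_torque_rows(self, small_knee_problem):
        names = [r.name for r in small_knee_problem.registry]
        assert "exo_torque_limits" in names

    def test_violation_reports_offending_constraint(self, small_problem):
        """A start violating the posture band is flagged by name."""
        viol, name = small_problem.max_violation(np.zeros(small_problem.n_x))
        assert viol > 0.1
        assert name == "posture_band"

    def test_hand_forward_violation_detected(self, subject, task):
        p = O.LiftingOptimization(subject, task, n_t=9)
        x = p.reference_start()
        # pitch the pelvis far backward so the wrist falls behind it
        x[body.GR1 * 5: (body.GR1 + 1) * 5] = -1.2
        ev = p.evaluate(x)
        row = next(r for r in p.registry if r.name == "hand_forward")
        assert np.min(ev.ineq[row.index]) < 0

    def test_angle_limits_are_control_point_bounds(self, small_problem):
        m = small_problem.model
        for i in body.ROTATIONAL_DOFS:
            s = slice(i * 5, (i + 1) * 5)
            assert np.all(small_problem.bounds[s, 0] == m.q_lower[i])
            assert np.all(small_problem.bounds[s, 1] == m.q_upper[i])

    def test_even_grid_rejected(self, subject, task):
        with pytest.raises(ValueError, match="odd"):
            O.LiftingOptimization(subject, task, n_t=10)


class TestWorkIntegral:
    def test_zero_torque_gives_zero_energy(self):
        w = np.full(5, 0.25)
        assert O.work_integral(np.zeros((5, 3)), np.ones((5, 3)), w) == 0.0

    def test_constant_torque_monotone_motion_closed_form(self):
        """Constant τ over a monotone excursion Δq yields |τ·Δq|."""
        n = 101
        t = np.linspace(0.0, 2.0, n)
        w = np.full(n, t[1] - t[0])
        w[[0, -1]] *= 0.5
        qd = np.full((n, 1), 0.7)          # Δq = 1.4 rad
        tau = np.full((n, 1), -12.0)
        assert O.work_integral(tau, qd, w) == pytest.approx(12.0 * 1.4)

    def test_positive_work_only_never_exceeds_absolute(self, rng):
        tau = rng.normal(size=(40, 7))
        qd = rng.normal(size=(40, 7))
        w = np.full(40, 0.05)
        assert (O.work_integral(tau, qd, w, positive_work_only=True)
                <= O.work_integral(tau, qd, w))


class TestReporting:
    def test_percent_reduction_identity_and_printed_peaks(self):
        assert O.percent_reduction(100.0, 100.0) == 0.0
        assert O.percent_reduction(268.60, 251.40) == pytest.approx(
            6.40, abs=0.005)
        assert O.percent_reduction(48.78, 30.24) == pytest.approx(
            38.01, abs=0.005)
        assert O.percent_reduction(154.42, 135.99) == pytest.approx(
            11.93, abs=0.005)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            O.percent_reduction(0.0, 1.0)
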