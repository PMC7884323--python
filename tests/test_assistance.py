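"""MPC cost/planner, force saturation and haptic-guidance trajectory tests."""

import numpy as np
import pytest
from scipy.linalg import expm

from swingsim import _core
from swingsim.assistance import (HgConfig, MpcConfig, Plan, apply_assist,
                                 hg_force, hg_trajectory, mpc_cost, mpc_plan)
from swingsim.dynamics import (AssistPoint, EndEffectorModel, PendulumParams,
                               SimState)
from swingsim.task import Slot, TargetSpec


def _target(y=0.12, impact=1.0):
    return TargetSpec(index=0, slot=Slot.RIGHT, y_target=y, impact_time=impact)


def _plan_from(forces, times, states, point=AssistPoint.END_EFFECTOR):
    return Plan(times=times, forces=forces, predicted_states=states,
                cost=0.0, application_point=point)


class TestMpcCost:
    def test_on_target_at_rest_costs_nothing(self, params):
        cfg = MpcConfig.for_end_effector()
        n = 10
        times = np.linspace(0.0, 1.0, n + 1)
        states = np.zeros((n + 1, 4))
        states[:, 0] = 0.12  # pivot directly above the target, ball below it
        plan = _plan_from(np.zeros(n), times, states)
        assert mpc_cost(plan, _target(0.12), cfg, params) == 0.0

    def test_matches_brute_force_summation(self, params, rng):
        cfg = MpcConfig.for_end_effector()
        n = 15
        times = np.linspace(0.0, 1.0, n + 1)
        states = rng.normal(0.0, 0.3, size=(n + 1, 4))
        forces = rng.normal(0.0, 2.0, size=n)
        plan = _plan_from(forces, times, states)
        target = _target(0.05)

        expected = 0.0  # independent term-by-term summation
        for k in range(1, n + 1):
            y, yd, th, thd = states[k]
            ball_y = y + params.l * np.sin(th)
            vy = yd + params.l * thd * np.cos(th)
            vz = params.l * thd * np.sin(th)
            tau = target.impact_time - times[k]
            expected += cfg.dist_weight(tau) * (ball_y - target.y_target) ** 2
            expected += cfg.w_speed * (vy ** 2 + vz ** 2)
            expected += cfg.force_weight(tau) * forces[k - 1] ** 2
        assert mpc_cost(plan, target, cfg, params) == pytest.approx(
            expected, abs=1e-10)

    def test_force_term_scales_quadratically(self, params, rng):
        cfg = MpcConfig.for_end_effector(w_dist=0.0, w_speed=0.0)
        n = 8
        times = np.linspace(0.0, 1.0, n + 1)
        states = rng.normal(0.0, 0.1, size=(n + 1, 4))
        forces = rng.normal(0.0, 1.0, size=n)
        c1 = mpc_cost(_plan_from(forces, times, states), _target(), cfg, params)
        c2 = mpc_cost(_plan_from(2 * forces, times, states), _target(), cfg,
                      params)
        assert c2 == pytest.approx(4 * c1, rel=1e-12)

    def test_mismatched_grid_rejected(self, params):
        with pytest.raises(ValueError):
            _plan_from(np.zeros(5), np.linspace(0, 1, 5), np.zeros((5, 4)))


class TestApplyAssist:
    def test_clamps_to_end_effector_limit(self):
        cfg = MpcConfig.for_end_effector()
        n = 4
        plan = _plan_from(np.full(n, 12.0), np.linspace(0, 1, n + 1),
                          np.zeros((n + 1, 4)))
        out = apply_assist(plan, 0.0, cfg)
        assert out.F_assist_y == 8.0
        assert out.assist_point is AssistPoint.END_EFFECTOR

    def test_inside_ball_limit_passes_through(self):
        cfg = MpcConfig.for_ball()
        plan = _plan_from(np.full(4, 0.5), np.linspace(0, 1, 5),
                          np.zeros((5, 4)), AssistPoint.BALL)
        assert apply_assist(plan, 0.0, cfg).F_assist_y == 0.5

    def test_assistance_off_is_identically_zero(self):
        cfg = MpcConfig.for_end_effector()
        plan = _plan_from(np.full(4, 5.0), np.linspace(0, 1, 5),
                          np.zeros((5, 4)))
        out = apply_assist(plan, 0.0, cfg, assistance_on=False)
        assert out.F_assist_y == 0.0
        assert out.assist_point is AssistPoint.NONE


class TestMpcPlan:
    def test_prohibitive_force_weight_yields_zero_plan(self, params, ee_model):
        cfg = MpcConfig.for_end_effector(w_force_base=1e9,
                                         force_schedule="constant")
        plan = mpc_plan(SimState(theta=0.2), _target(), cfg, params, ee_model)
        assert np.abs(plan.forces).max() < 1e-4

    def test_deterministic(self, params, ee_model):
        cfg = MpcConfig.for_end_effector()
        st = SimState(y=0.02, theta=0.1, theta_dot=-0.4)
        a = mpc_plan(st, _target(), cfg, params, ee_model)
        b = mpc_plan(st, _target(), cfg, params, ee_model)
        assert np.array_equal(a.forces, b.forces)
        assert a.cost == b.cost

    def test_first_force_matches_linear_quadratic_oracle(self, params,
                                                         ee_model):
        """Small-angle ball-force planning vs an independent LQ tracking solve.

        The oracle discretizes the analytically linearized plant with a
        zero-order hold (matrix exponential) and solves the unconstrained
        weighted least-squares tracking problem in closed form.
        """
        cfg = MpcConfig.for_ball(force_limit=1e3)
        p, ee = params, ee_model
        a = np.zeros((4, 4))
        b = np.zeros((4, 1))
        a[0, 1] = 1.0
        a[2, 3] = 1.0
        a[1, 1] = -ee.b_ee / ee.m_ee
        a[1, 2] = p.m * p.g / ee.m_ee
        a[3, :] = -(p.g * np.array([0, 0, 1, 0]) + a[1, :]) / p.l
        a[3, 3] += -p.c / (p.m * p.l ** 2)
        b[3, 0] = 1.0 / (p.m * p.l)

        tti = 1.0
        n = 40
        dt = tti / n
        aug = np.zeros((5, 5))
        aug[:4, :4] = a * dt
        aug[:4, 4:] = b * dt
        ea = expm(aug)
        ad, bd = ea[:4, :4], ea[:4, 4:]

        x0 = np.array([0.01, 0.0, 0.02, 0.0])
        target_y = 0.05
        tau = tti - dt * np.arange(1, n + 1)
        wd = np.array([cfg.dist_weight(t) for t in tau])
        wf = np.array([cfg.force_weight(t) for t in tau])
        c_pos = np.array([1.0, 0.0, p.l, 0.0])
        c_vel = np.array([0.0, 1.0, 0.0, p.l])

        powers = [np.eye(4)]
        for _ in range(n):
            powers.append(ad @ powers[-1])
        rows, rhs = [], []
        for k in range(1, n + 1):
            sens = np.zeros((4, n))
            for j in range(k):
                sens[:, j] = (powers[k - 1 - j] @ bd).ravel()
            xk_free = powers[k] @ x0
            rows.append(np.sqrt(wd[k - 1]) * (c_pos @ sens))
            rhs.append(-np.sqrt(wd[k - 1]) * (c_pos @ xk_free - target_y))
            rows.append(np.sqrt(cfg.w_speed) * (c_vel @ sens))
            rhs.append(-np.sqrt(cfg.w_speed) * (c_vel @ xk_free))
        for k in range(n):
            e = np.zeros(n)
            e[k] = np.sqrt(wf[k])
            rows.append(e)
            rhs.append(0.0)
        u_oracle, *_ = np.linalg.lstsq(np.vstack(rows), np.array(rhs),
                                       rcond=None)

        plan = mpc_plan(SimState(y=0.01, theta=0.02), _target(target_y, tti),
                        cfg, params, ee_model)
        assert plan.forces[0] == pytest.approx(u_oracle[0], rel=0.05)

    def test_replanning_reproduces_previous_tail(self, params, ee_model):
        """With a perfect model and no disturbance, the receding horizon is
        consistent: the new solution continues the old plan."""
        cfg = MpcConfig.for_end_effector()
        st = SimState(theta=0.1, theta_dot=0.5)
        tg = _target()
        plan = mpc_plan(st, tg, cfg, params, ee_model)
        dtp = plan.times[1] - plan.times[0]
        x1 = _core.plan_rollout(
            np.array([st.y, st.y_dot, st.theta, st.theta_dot]),
            plan.forces[:1], dtp, False, params.m, params.l, params.g,
            params.c, ee_model.m_ee, ee_model.b_ee)[1]
        st1 = SimState(t=st.t + dtp, y=x1[0], y_dot=x1[1], theta=x1[2],
                       theta_dot=x1[3])
        plan2 = mpc_plan(st1, tg, cfg, params, ee_model,
                         warm_start=plan.forces[1:])
        tail = plan.forces[1:]
        n = min(len(tail), len(plan2.forces))
        rel = (np.linalg.norm(plan2.forces[:n] - tail[:n])
               / np.linalg.norm(tail[:n]))
        assert rel < 1e-3

    def test_rejects_past_impact(self, params, ee_model):
        with pytest.raises(ValueError):
            mpc_plan(SimState(t=2.0), _target(impact=1.0),
                     MpcConfig.for_end_effector(), params, ee_model)


class TestHapticGuidance:
    def test_spline_reproduces_optimizer_waypoints(self, params, ee_model):
        cfg = MpcConfig.for_end_effector()
        traj = hg_trajectory(SimState(theta=0.05), _target(), cfg, params,
                             ee_model)
        fitted = traj.position(traj.knot_times)
        assert np.abs(fitted - traj.waypoints).max() < 1e-6

    def test_trajectory_is_frozen(self, params, ee_model):
        cfg = MpcConfig.for_end_effector()
        st = SimState(theta=0.05)
        traj = hg_trajectory(st, _target(), cfg, params, ee_model)
        probe = np.linspace(0.0, 1.0, 50)
        before = traj.position(probe).copy()
        # the actual system moves on; the fitted trajectory must not care
        after = traj.position(probe)
        assert np.array_equal(before, after)
        traj2 = hg_trajectory(st, _target(), cfg, params, ee_model)
        assert np.array_equal(before, traj2.position(probe))

    def test_predicted_ball_lands_on_target_from_on_path_state(self, params,
                                                                ee_model):
        # mid-approach state taken from the optimizer's own plan: the
        # refitted trajectory predicts the ball on target to within 1 mm
        cfg = MpcConfig.for_end_effector()
        tg = _target(0.05)
        plan = mpc_plan(SimState(), tg, cfg, params, ee_model)
        x = plan.predicted_states[16]
        st = SimState(t=plan.times[16], y=x[0], y_dot=x[1], theta=x[2],
                      theta_dot=x[3])
        traj = hg_trajectory(st, tg, cfg, params, ee_model)
        assert abs(traj.predicted_ball_y_at_impact - 0.05) < 1e-3

    def test_pd_force_values(self):
        cfg = HgConfig()  # P 100, D 20, per 0.6 kg of pendulum mass

        class _Traj:
            def position(self, t):
                return 0.01

            def velocity(self, t):
                return 0.0

        st = SimState(y=0.0, y_dot=0.0)
        assert hg_force(st, _Traj(), cfg) == pytest.approx(0.6)

        st_on = SimState(y=0.01, y_dot=0.0)
        assert hg_force(st_on, _Traj(), cfg) == 0.0

        class _Far:
            def position(self, t):
                return 0.5

            def velocity(self, t):
                return 0.0

        assert hg_force(st, _Far(), cfg) == 8.0  # clamped at the limit
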