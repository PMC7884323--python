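"""Robotic assistance strategies for the pendulum hitting task.

Three strategies are implemented, all acting only along the lateral (y)
axis:

* **end-effector MPC** — receding-horizon optimal control recomputed at
  80 Hz, force applied on the pivot the participant holds, saturated at 8 N;
* **ball MPC** — the same optimization but with the force applied directly
  at the pendulum ball, saturated at 1 N;
* **haptic guidance (HG)** — one trajectory optimization per target, a cubic
  B-spline fit to the optimal end-effector path, tracked by a PD controller
  saturated at 8 N.

The shared optimization minimizes a quadratic cost over the horizon from
"now" to the current target's wall impact: lateral ball-to-target distance,
ball linear speed, and assisting force, each weighted per step.  The force
weight shrinks proportionally to the remaining time to impact, so the
controller leaves the participant free early in the approach and intervenes
mostly near impact.  The solver is a projected Gauss-Newton iteration on a
direct single-shooting parameterization with a fixed iteration budget,
warm-started from the shifted previous solution — a deterministic, offline
stand-in for a real-time-iteration NLP solver.

The optimizer's internal model treats the participant as a passive
admittance (zero future hand force); robustness to the actual hand input
comes from the high replanning rate, not from predicting the human.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from . import _core
from .dynamics import AssistPoint, EndEffectorModel, ForceInput, PendulumParams, SimState
from .task import TargetSpec

__all__ = [
    "MpcConfig",
    "Plan",
    "HgConfig",
    "HgTrajectory",
    "mpc_cost",
    "mpc_plan",
    "apply_assist",
    "hg_trajectory",
    "hg_force",
    "MpcController",
    "HgController",
    "NullController",
]


@dataclass(frozen=True)
class MpcConfig:
    """Tunable parameters of the receding-horizon optimizer.

    The base weights (w_dist [1/m^2], w_speed [s^2/m^2], w_force_base
    [1/N^2]) set the relative price of miss distance, ball speed and assist
    effort; ``force_schedule`` maps time-to-impact (normalized by
    ``schedule_tau_max``) to a force-weight multiplier.  Defaults were
    calibrated so that the end-effector controller at its 8 N limit guides a
    fully passive participant to within a centimetre of each target.
    """

    replan_rate: float = 80.0          # Hz
    plan_dt: float = 0.025             # s, shooting grid spacing
    max_steps: int = 40                # horizon cap (one target interval)
    w_dist: float = 60.0
    w_speed: float = 0.5
    w_force_base: float = 4e-3
    force_schedule: str = "linear"     # "linear" (in time-to-impact) or "constant"
    dist_schedule: str = "ramp"        # "ramp" (grows toward impact) or "constant"
    dist_ramp_power: float = 2.0       # ramp sharpness; higher focuses on impact
    schedule_tau_max: float = 1.0      # s, normalization of both schedules
    force_limit: float = 8.0           # N
    application_point: AssistPoint = AssistPoint.END_EFFECTOR
    sqp_iters: int = 5
    cold_start_iters: int = 20         # budget for the first solve of a target
    increment_reg: float = 1e-9        # stabilizing quadratic regularizer

    def __post_init__(self) -> None:
        if min(self.w_dist, self.w_speed, self.w_force_base) < 0:
            raise ValueError("weights must be non-negative")
        if self.force_limit <= 0:
            raise ValueError("force_limit must be positive")
        if self.application_point is AssistPoint.NONE:
            raise ValueError("MPC needs an application point")
        if self.force_schedule not in ("linear", "constant"):
            raise ValueError("force_schedule must be 'linear' or 'constant'")
        if self.dist_schedule not in ("ramp", "constant"):
            raise ValueError("dist_schedule must be 'ramp' or 'constant'")

    def force_weight(self, tau: float) -> float:
        """Per-step force weight w_F as a function of time-to-impact tau [s]."""
        if self.force_schedule == "constant":
            return self.w_force_base
        return self.w_force_base * max(0.0, tau) / self.schedule_tau_max

    def dist_weight(self, tau: float) -> float:
        """Per-step distance weight, growing as the wall approaches.

        The accuracy requirement is really about the instant of wall impact,
        so with the default "ramp" the miss distance is priced in proportion
        to how close (in time) the wall is, vanishing at a full interval out
        and maximal at impact — the mirror image of the force schedule.
        """
        if self.dist_schedule == "constant":
            return self.w_dist
        frac = 1.0 - max(0.0, tau) / self.schedule_tau_max
        return self.w_dist * max(0.0, frac) ** self.dist_ramp_power

    @classmethod
    def for_end_effector(cls, **kw) -> "MpcConfig":
        kw.setdefault("force_limit", 8.0)
        kw.setdefault("application_point", AssistPoint.END_EFFECTOR)
        return cls(**kw)

    @classmethod
    def for_ball(cls, **kw) -> "MpcConfig":
        kw.setdefault("force_limit", 1.0)
        kw.setdefault("application_point", AssistPoint.BALL)
        return cls(**kw)


@dataclass(frozen=True)
class Plan:
    """One solved open-loop plan over the to-impact horizon.

    ``times`` has N+1 entries (now .. impact); ``forces`` has N entries,
    zero-order held on each interval; ``predicted_states`` rows are
    ``[y, y_dot, theta, theta_dot]`` of the planning model.
    """

    times: np.ndarray
    forces: np.ndarray
    predicted_states: np.ndarray
    cost: float
    application_point: AssistPoint
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.times) != len(self.forces) + 1:
            raise ValueError("times must have one more entry than forces")
        if self.predicted_states.shape[0] != len(self.times):
            raise ValueError("predicted_states must align with times")


@dataclass(frozen=True)
class HgConfig:
    """Haptic-guidance PD parameters.

    The published gains are normalized per kilogram of moved mass
    (P: 100 N/m/kg, D: 20 N s/m/kg); ``mass_scale`` converts them to
    absolute gains and defaults to the pendulum ball mass.
    """

    P: float = 100.0
    D: float = 20.0
    mass_scale: float = 0.6
    spline_degree: int = 3
    force_limit: float = 8.0

    def __post_init__(self) -> None:
        if min(self.P, self.D, self.force_limit, self.mass_scale) <= 0:
            raise ValueError("HG gains, mass scale and force limit must be positive")

    @property
    def P_eff(self) -> float:
        return self.P * self.mass_scale

    @property
    def D_eff(self) -> float:
        return self.D * self.mass_scale


def _ball_terms(params: PendulumParams, x: np.ndarray):
    """Ball lateral position and velocity components from a planning state."""
    y, yd, th, thd = x
    sin, cos = math.sin(th), math.cos(th)
    ball_y = y + params.l * sin
    vy = yd + params.l * thd * cos
    vz = params.l * thd * sin
    return ball_y, vy, vz


def mpc_cost(plan: Plan, target: TargetSpec, config: MpcConfig,
             params: PendulumParams | None = None) -> float:
    """Evaluate the quadratic tracking cost of a plan.

    Sum over horizon steps k = 1..N of ``w_dist d_k^2 + w_speed v_k^2 +
    w_F(tau_k) F_k^2`` with d_k the predicted lateral ball-to-target
    distance, v_k the ball linear speed and tau_k the remaining time to
    impact.
    """
    params = params or PendulumParams()
    n = len(plan.forces)
    if plan.predicted_states.shape[0] != n + 1:
        raise ValueError("plan grid lengths are inconsistent")
    total = 0.0
    for k in range(1, n + 1):
        ball_y, vy, vz = _ball_terms(params, plan.predicted_states[k])
        tau = target.impact_time - plan.times[k]
        d = ball_y - target.y_target
        total += (config.dist_weight(tau) * d * d
                  + config.w_speed * (vy * vy + vz * vz)
                  + config.force_weight(tau) * plan.forces[k - 1] ** 2)
    return float(total)


def _horizon_grid(now: float, impact: float, config: MpcConfig):
    tti = impact - now
    if tti <= 0:
        raise ValueError("time to impact must be positive")
    n = max(1, min(config.max_steps, int(math.ceil(tti / config.plan_dt - 1e-9))))
    dt = tti / n
    return n, dt


def mpc_plan(state: SimState, target: TargetSpec, config: MpcConfig,
             params: PendulumParams | None = None,
             ee_model: EndEffectorModel | None = None,
             warm_start: np.ndarray | None = None) -> Plan:
    """Solve the to-impact optimal assistance problem from the current state.

    The shooting grid spans now .. impact with at most ``max_steps`` steps
    (the step length stretches to land exactly on the impact time).  A fixed
    Gauss-Newton iteration budget and deterministic initialization (zeros,
    or the caller-supplied warm start) make the result reproducible; if the
    iteration has not converged the last iterate is returned with
    ``converged=False`` rather than raising mid-episode.
    """
    params = params or PendulumParams()
    ee_model = ee_model or EndEffectorModel()
    n, dt = _horizon_grid(state.t, target.impact_time, config)

    f_init = np.zeros(n)
    if warm_start is not None:
        k = min(n, len(warm_start))
        f_init[:k] = warm_start[:k]
        if k and k < n:
            f_init[k:] = warm_start[k - 1]

    times = state.t + dt * np.arange(n + 1)
    tau = target.impact_time - times[1:]
    sq_wf = np.sqrt(np.array([config.force_weight(tk) for tk in tau]))
    sq_wd = np.sqrt(np.array([config.dist_weight(tk) for tk in tau]))
    x0 = np.array([state.y, state.y_dot, state.theta, state.theta_dot])
    at_ball = config.application_point is AssistPoint.BALL
    iters = config.sqp_iters if warm_start is not None else config.cold_start_iters

    forces, cost = _core.mpc_solve(
        x0, f_init, dt, at_ball,
        params.m, params.l, params.g, params.c, ee_model.m_ee, ee_model.b_ee,
        target.y_target, sq_wd, math.sqrt(config.w_speed),
        sq_wf, config.force_limit, iters, config.increment_reg)

    states = _core.plan_rollout(x0, forces, dt, at_ball,
                                params.m, params.l, params.g, params.c,
                                ee_model.m_ee, ee_model.b_ee)
    converged = bool(np.all(np.isfinite(forces)) and math.isfinite(cost))
    if not converged:  # fall back to the (clipped) initial guess
        forces = np.clip(f_init, -config.force_limit, config.force_limit)
        states = _core.plan_rollout(x0, forces, dt, at_ball,
                                    params.m, params.l, params.g, params.c,
                                    ee_model.m_ee, ee_model.b_ee)
        cost = float("nan")
    return Plan(times=times, forces=forces, predicted_states=states,
                cost=float(cost), application_point=config.application_point,
                converged=converged)


def apply_assist(plan: Plan, now: float, config: MpcConfig,
                 assistance_on: bool = True) -> ForceInput:
    """Force to apply right now from a plan: first covering interval, clamped.

    With assistance off (catch blocks) the contribution is identically zero.
    A plan older than its horizon yields its last force, zero-order held.
    """
    if not assistance_on:
        return ForceInput()
    idx = int(np.searchsorted(plan.times, now, side="right")) - 1
    idx = min(max(idx, 0), len(plan.forces) - 1)
    f = float(np.clip(plan.forces[idx], -config.force_limit, config.force_limit))
    return ForceInput(F_assist_y=f, assist_point=plan.application_point)


class HgTrajectory:
    """A frozen desired end-effector trajectory for one target.

    Wraps a cubic B-spline through the optimizer's waypoints; evaluation is
    clamped to the fitted time span.  ``fallback`` marks the straight-line
    trajectory used when the optimization failed.
    """

    def __init__(self, times: np.ndarray, waypoints: np.ndarray,
                 degree: int = 3, fallback: bool = False,
                 predicted_ball_y_at_impact: float = float("nan")):
        self.t0 = float(times[0])
        self.t1 = float(times[-1])
        self.knot_times = np.asarray(times, dtype=float)
        self.waypoints = np.asarray(waypoints, dtype=float)
        self.fallback = fallback
        self.predicted_ball_y_at_impact = predicted_ball_y_at_impact
        k = min(degree, len(times) - 1)
        self._spline = make_interp_spline(times, waypoints, k=k)
        self._dspline = self._spline.derivative()

    def _clamp(self, t):
        return np.clip(t, self.t0, self.t1)

    def position(self, t):
        return self._spline(self._clamp(t))

    def velocity(self, t):
        return self._dspline(self._clamp(t))


def hg_trajectory(state: SimState, target: TargetSpec, config: MpcConfig,
                  params: PendulumParams | None = None,
                  ee_model: EndEffectorModel | None = None,
                  spline_degree: int = 3) -> HgTrajectory:
    """Fit the per-target guidance trajectory (called once per target).

    Runs the same trajectory optimization as the MPC once, then fits a cubic
    B-spline through the optimal end-effector lateral path over
    [now, impact].  The result is frozen: later state changes do not affect
    it.  On optimization failure a straight line from the current pivot
    position to a point above the target is returned, flagged as fallback.
    """
    params = params or PendulumParams()
    plan = mpc_plan(state, target, config, params, ee_model)
    if plan.converged:
        ball_y, _, _ = _ball_terms(params, plan.predicted_states[-1])
        return HgTrajectory(plan.times, plan.predicted_states[:, 0].copy(),
                            degree=spline_degree,
                            predicted_ball_y_at_impact=ball_y)
    times = np.linspace(state.t, target.impact_time, 4)
    way = np.linspace(state.y, target.y_target, 4)
    return HgTrajectory(times, way, degree=1, fallback=True)


def hg_force(state: SimState, trajectory: HgTrajectory, config: HgConfig,
             now: float | None = None) -> float:
    """PD guidance force toward the frozen trajectory, clamped to the limit."""
    t = state.t if now is None else now
    e = float(trajectory.position(t)) - state.y
    ed = float(trajectory.velocity(t)) - state.y_dot
    f = config.P_eff * e + config.D_eff * ed
    return float(np.clip(f, -config.force_limit, config.force_limit))


# ---------------------------------------------------------------------------
# stateful controller wrappers used by the protocol runner
# ---------------------------------------------------------------------------


class NullController:
    """No assistance (control group, catch blocks, tests)."""

    application_point = AssistPoint.NONE

    def start_target(self, state: SimState, target: TargetSpec) -> None:
        pass

    def update(self, state: SimState, target: TargetSpec) -> float:
        return 0.0


class MpcController:
    """Receding-horizon controller: replans from the current state at each call.

    The warm start is the previous solution shifted by the elapsed grid
    steps, which makes successive solutions consistent along the horizon.
    """

    def __init__(self, config: MpcConfig,
                 params: PendulumParams | None = None,
                 ee_model: EndEffectorModel | None = None):
        self.config = config
        self.params = params or PendulumParams()
        self.ee_model = ee_model or EndEffectorModel()
        self.application_point = config.application_point
        self._plan: Plan | None = None

    def start_target(self, state: SimState, target: TargetSpec) -> None:
        self._plan = None

    def update(self, state: SimState, target: TargetSpec) -> float:
        warm = None
        if self._plan is not None:
            shift = int(round((state.t - self._plan.times[0]) /
                              max(self._plan.times[1] - self._plan.times[0], 1e-9)))
            shift = max(0, shift)
            warm = self._plan.forces[shift:] if shift < len(self._plan.forces) \
                else self._plan.forces[-1:]
        self._plan = mpc_plan(state, target, self.config, self.params,
                              self.ee_model, warm_start=warm)
        return apply_assist(self._plan, state.t, self.config).F_assist_y


class HgController:
    """Per-target frozen-trajectory guidance with PD tracking."""

    def __init__(self, hg_config: HgConfig | None = None,
                 mpc_config: MpcConfig | None = None,
                 params: PendulumParams | None = None,
                 ee_model: EndEffectorModel | None = None):
        self.hg_config = hg_config or HgConfig()
        self.mpc_config = mpc_config or MpcConfig.for_end_effector()
        self.params = params or PendulumParams()
        self.ee_model = ee_model or EndEffectorModel()
        self.application_point = AssistPoint.END_EFFECTOR
        self._trajectory: HgTrajectory | None = None
        self.fit_count = 0
        self.fits_per_target: list[int] = []

    def start_target(self, state: SimState, target: TargetSpec) -> None:
        self._trajectory = hg_trajectory(state, target, self.mpc_config,
                                         self.params, self.ee_model,
                                         spline_degree=self.hg_config.spline_degree)
        self.fit_count += 1
        self.fits_per_target.append(1)

    def update(self, state: SimState, target: TargetSpec) -> float:
        if self._trajectory is None:
            self.start_target(state, target)
        return hg_force(state, self._trajectory, self.hg_config)
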