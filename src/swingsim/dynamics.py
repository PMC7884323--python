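"""Planar pendulum dynamics with haptic rod-force rendering.

The simulated plant is the virtual pendulum of the training task: a point
ball of mass ``m`` on a massless rigid rod of length ``l``, hanging from a
pivot that coincides with the robot end-effector the participant holds.
Gravity is reduced (default one third of Earth's) to slow the swing to a
comfortable desk-scale tempo, and the rotational damping ``c`` is nearly
zero so the pendulum does not stabilise itself.

Conventions: ``y`` points right, ``z`` up, and the internal angle ``theta``
is measured counter-clockwise from the straight-down configuration, so the
ball sits at ``(y + l sin(theta), z - l cos(theta))``.  ``theta`` is
integrated unwrapped (never reduced modulo 2*pi) so spectral analysis of the
swing sees a continuous angle.

The pivot itself is modelled as an admittance — an apparent mass plus
viscous damping standing in for the coupled hand + end-effector — driven by
the participant's hand force, any assistance force applied at the
end-effector, and the rod reaction force of the pendulum.  The rod force is
what a haptic device would render to the hand.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from . import _core

__all__ = [
    "PendulumParams",
    "SimState",
    "EndEffectorModel",
    "AssistPoint",
    "ForceInput",
    "theta_ddot",
    "rod_force",
    "step",
    "natural_frequency",
    "ball_position",
    "simulate_free_pendulum",
    "zero_crossing_frequency",
]

MAX_DT = 5e-3  # s; fixed-step integration is only trusted below this


@dataclass(frozen=True)
class PendulumParams:
    """Physical constants of the rendered pendulum.

    m : ball mass [kg]; l : rod length [m]; g : effective gravity [m/s^2];
    c : rotational viscous damping [N m s/rad] acting on theta_dot.
    ``m = 0`` is accepted as a degenerate "pendulum removed" mode used to
    verify the pivot admittance in isolation.
    """

    m: float = 0.6
    l: float = 0.25
    g: float = 9.81 / 3.0
    c: float = 3e-6

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.m, self.l, self.g, self.c)):
            raise ValueError("pendulum parameters must be finite")
        if self.m < 0 or self.l <= 0 or self.g <= 0 or self.c < 0:
            raise ValueError(
                "require m >= 0, l > 0, g > 0, c >= 0 "
                f"(got m={self.m}, l={self.l}, g={self.g}, c={self.c})"
            )


@dataclass(frozen=True)
class SimState:
    """Instantaneous state: time, pivot kinematics and pendulum angle."""

    t: float = 0.0
    y: float = 0.0
    z: float = 0.0
    y_dot: float = 0.0
    z_dot: float = 0.0
    theta: float = 0.0
    theta_dot: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.t, self.y, self.z, self.y_dot, self.z_dot,
                self.theta, self.theta_dot)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("state must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([self.y, self.z, self.y_dot, self.z_dot,
                         self.theta, self.theta_dot])

    @classmethod
    def from_array(cls, t: float, s: np.ndarray) -> "SimState":
        return cls(t=t, y=s[0], z=s[1], y_dot=s[2], z_dot=s[3],
                   theta=s[4], theta_dot=s[5])


@dataclass(frozen=True)
class EndEffectorModel:
    """Admittance model of the coupled hand + end-effector.

    m_ee : apparent mass [kg] per axis; b_ee : viscous damping [N s/m].
    ``m_ee = inf`` clamps the pivot in place (used for free-swing analysis).
    """

    m_ee: float = 0.3
    b_ee: float = 2.0

    def __post_init__(self) -> None:
        if not (self.m_ee > 0):
            raise ValueError("m_ee must be positive (inf allowed for a clamped pivot)")
        if not (self.b_ee >= 0 and math.isfinite(self.b_ee)):
            raise ValueError("b_ee must be finite and non-negative")

    @property
    def clamped(self) -> bool:
        return math.isinf(self.m_ee)

    @classmethod
    def clamped_pivot(cls) -> "EndEffectorModel":
        return cls(m_ee=math.inf, b_ee=0.0)


class AssistPoint(enum.Enum):
    """Where an assistance force acts. z-axis assistance does not exist."""

    NONE = "none"
    END_EFFECTOR = "end_effector"
    BALL = "ball"


@dataclass(frozen=True)
class ForceInput:
    """Forces applied during one integration step.

    Hand forces act on the pivot; the single lateral assistance force acts
    either on the pivot (end-effector) or directly on the ball, never on z.
    """

    F_hand_y: float = 0.0
    F_hand_z: float = 0.0
    F_assist_y: float = 0.0
    assist_point: AssistPoint = AssistPoint.NONE

    def __post_init__(self) -> None:
        vals = (self.F_hand_y, self.F_hand_z, self.F_assist_y)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("forces must be finite")
        if self.assist_point is AssistPoint.NONE and self.F_assist_y != 0.0:
            raise ValueError("non-zero assist force requires an application point")


def _check_finite(*vals: float) -> None:
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("inputs must be finite")


def theta_ddot(state: SimState, y_ddot: float, z_ddot: float,
               params: PendulumParams, F_ball_y: float = 0.0) -> float:
    """Angular acceleration of the pendulum given the pivot acceleration.

    theta_ddot = -(1/l)((z_ddot + g) sin th + y_ddot cos th)
                 - c/(m l^2) theta_dot + F_ball_y cos th / (m l)

    The last term is the tangential effect of a horizontal force applied
    directly at the ball (zero for the plain rendered pendulum).
    """
    _check_finite(y_ddot, z_ddot, F_ball_y)
    if params.m <= 0:
        raise ValueError("theta_ddot undefined for the pendulum-removed mode (m=0)")
    th, thd = state.theta, state.theta_dot
    return (-((z_ddot + params.g) * math.sin(th) + y_ddot * math.cos(th)) / params.l
            - params.c / (params.m * params.l ** 2) * thd
            + F_ball_y * math.cos(th) / (params.m * params.l))


def rod_force(state: SimState, y_ddot: float, z_ddot: float,
              params: PendulumParams, F_ball_y: float = 0.0):
    """Rod force rendered at the pivot.

    Returns ``(scalar, (Fy, Fz))``: the scalar tension
    ``m ((z_ddot + g) cos th - y_ddot sin th + theta_dot^2 l)`` (plus the
    along-rod component of any ball force) and its components along the
    pivot->ball direction ``(sin th, -cos th)`` — i.e. the force the haptic
    device applies to the hand.
    """
    _check_finite(y_ddot, z_ddot, F_ball_y)
    th, thd = state.theta, state.theta_dot
    scalar = params.m * ((z_ddot + params.g) * math.cos(th)
                         - y_ddot * math.sin(th) + thd ** 2 * params.l)
    scalar += F_ball_y * math.sin(th)
    return scalar, (scalar * math.sin(th), -scalar * math.cos(th))


def step(state: SimState, forces: ForceInput, dt: float,
         ee_model: EndEffectorModel, params: PendulumParams) -> SimState:
    """Advance the coupled pivot + pendulum system one RK4 step.

    Forces are held constant over the step (zero-order hold between
    controller updates).  ``dt`` must lie in (0, 5 ms].
    """
    if not (0.0 < dt <= MAX_DT):
        raise ValueError(f"dt must be in (0, {MAX_DT}] s, got {dt}")
    f_py = forces.F_hand_y
    f_ball = 0.0
    if forces.assist_point is AssistPoint.END_EFFECTOR:
        f_py += forces.F_assist_y
    elif forces.assist_point is AssistPoint.BALL:
        f_ball = forces.F_assist_y
    m_ee = ee_model.m_ee if not ee_model.clamped else 1.0
    s = _core.rk4_step(state.to_array(), f_py, forces.F_hand_z, f_ball, dt,
                       params.m, params.l, params.g, params.c,
                       m_ee, ee_model.b_ee, ee_model.clamped)
    return SimState.from_array(state.t + dt, s)


def natural_frequency(params: PendulumParams) -> float:
    """Small-oscillation frequency sqrt(g/l) / (2 pi), in Hz."""
    return math.sqrt(params.g / params.l) / (2.0 * math.pi)


def ball_position(state: SimState, params: PendulumParams):
    """Cartesian ball position ``(y + l sin th, z - l cos th)``."""
    return (state.y + params.l * math.sin(state.theta),
            state.z - params.l * math.cos(state.theta))


def simulate_free_pendulum(theta0: float, duration: float,
                           params: PendulumParams | None = None,
                           dt: float = 1e-3,
                           theta_dot0: float = 0.0):
    """Free swing with the pivot clamped; returns ``(t, theta)`` arrays."""
    params = params or PendulumParams()
    if not (0.0 < dt <= MAX_DT):
        raise ValueError(f"dt must be in (0, {MAX_DT}] s, got {dt}")
    n = int(round(duration / dt))
    theta = _core.simulate_clamped(theta0, theta_dot0, n, dt,
                                   params.m, params.l, params.g, params.c)
    t = np.arange(n + 1) * dt
    return t, theta


def zero_crossing_frequency(t: np.ndarray, x: np.ndarray) -> float:
    """Oscillation frequency from linearly interpolated zero crossings.

    Uses the mean interval between successive same-direction crossings of
    the mean-removed signal; needs at least two full periods.
    """
    x = np.asarray(x, dtype=float) - np.mean(x)
    sgn = np.signbit(x)
    up = np.nonzero(sgn[:-1] & ~sgn[1:])[0]
    if up.size < 2:
        raise ValueError("need at least two rising zero crossings")
    # interpolate crossing times for sub-sample resolution
    tc = t[up] + (t[up + 1] - t[up]) * (-x[up]) / (x[up + 1] - x[up])
    return float((tc.size - 1) / (tc[-1] - tc[0]))
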