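"""Synthetic participants that close the simulation loop.

These surrogates stand in for human subjects so the assistance controllers
can be exercised across skill levels.  They are deliberately *not* models of
human motor learning: a surrogate's skill is fixed, and learning curves are
out of scope.  A surrogate

* plans an intended end-effector trajectory for each target using the same
  trajectory optimizer as the assistance module, but with an *internal model
  of the pendulum corrupted* in proportion to (1 - skill) — at skill 0 the
  perceived rod length and gravity are biased by up to +/-30 %;
* tracks that intent with a hand PD controller acting on a reference
  evaluated ``reaction_delay`` seconds in the past, plus Gaussian motor
  noise (held piecewise-constant at 20 Hz, i.e. band-limited like muscle
  force fluctuations);
* "slacks": the lateral hand effort (tracking drive and its
  signal-dependent noise) is scaled down by
  ``1 - slack_gain * min(1, |assist| / limit)`` when it perceives the robot
  working, the standard observation that people reduce effort under
  assistance;
* always stabilises the vertical axis with a PD about a home height
  (the arm rests on the table; z support is never slacked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .assistance import MpcConfig, mpc_plan
from .dynamics import AssistPoint, EndEffectorModel, PendulumParams, SimState
from .task import TargetSpec

__all__ = ["ParticipantParams", "Intent", "Participant", "PRESETS", "preset",
           "motor_noise"]

MODEL_BIAS_MAX = 0.3       # fractional parameter error at skill 0
NOISE_HOLD_HZ = 20.0       # motor-noise bandwidth (sample-and-hold rate)
INTENT_FORCE_CAP = 25.0    # N; voluntary planning assumes human-scale effort


@dataclass(frozen=True)
class ParticipantParams:
    """Tunable description of one surrogate participant.

    skill in [0, 1] scales internal-model fidelity; noise_sd [N] is the
    motor-noise std; reaction_delay [s] lags the tracked reference;
    hand_P [N/m] / hand_D [N s/m] are lateral tracking gains; slack_gain in
    [0, 1] is the maximal fractional effort reduction under assistance.
    ``stiffen_gain`` scales the impedance up-regulation against forces felt
    at the hand (people co-contract when a robot pushes them around);
    ``replan_threshold`` [m] is the tracking error beyond which the
    surrogate abandons its current plan and re-plans from the actual state,
    the way people correct after a gross error rather than chasing a stale
    intention.
    """

    skill: float = 0.5
    noise_sd: float = 0.8
    reaction_delay: float = 0.12
    hand_P: float = 400.0
    hand_D: float = 40.0
    slack_gain: float = 0.5
    stiffen_gain: float = 0.6
    replan_threshold: float = 0.12
    rng_seed: int = 0
    z_P: float = 200.0
    z_D: float = 20.0
    z_home: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.skill <= 1.0 and 0.0 <= self.slack_gain <= 1.0):
            raise ValueError("skill and slack_gain must lie in [0, 1]")
        if self.stiffen_gain < 0:
            raise ValueError("stiffen_gain must be non-negative")
        if self.noise_sd < 0 or self.reaction_delay < 0:
            raise ValueError("noise_sd and reaction_delay must be non-negative")
        if min(self.hand_P, self.hand_D, self.z_P, self.z_D) < 0:
            raise ValueError("gains must be non-negative")


PRESETS: dict[str, ParticipantParams] = {
    # passive: hangs on to the handle, no voluntary lateral effort
    "passive": ParticipantParams(skill=0.0, noise_sd=0.0, reaction_delay=0.0,
                                 hand_P=0.0, hand_D=0.0, slack_gain=0.0,
                                 stiffen_gain=0.0),
    # novice: mid skill, noisy, slacks readily — the default study surrogate
    "novice": ParticipantParams(skill=0.5, noise_sd=0.8, reaction_delay=0.12,
                                hand_P=400.0, hand_D=40.0, slack_gain=0.5),
    # skilled: near-faithful internal model, small noise, little slacking
    "skilled": ParticipantParams(skill=0.9, noise_sd=0.3, reaction_delay=0.1,
                                 hand_P=600.0, hand_D=60.0, slack_gain=0.2,
                                 stiffen_gain=0.4),
    # ideal: perfect model, no noise, no delay, no slacking (upper bound)
    "ideal": ParticipantParams(skill=1.0, noise_sd=0.0, reaction_delay=0.0,
                               hand_P=800.0, hand_D=80.0, slack_gain=0.0,
                               stiffen_gain=0.0),
}


def preset(name: str, **overrides) -> ParticipantParams:
    return replace(PRESETS[name], **overrides)


@dataclass(frozen=True)
class Intent:
    """A planned end-effector reference path for one target."""

    times: np.ndarray
    y: np.ndarray
    y_dot: np.ndarray

    def position(self, t):
        return np.interp(t, self.times, self.y)

    def velocity(self, t):
        return np.interp(t, self.times, self.y_dot)


def motor_noise(n_steps: int, dt: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian motor noise: 20 Hz sample-and-hold at sim rate."""
    if sd == 0.0:
        return np.zeros(n_steps)
    hold = max(1, int(round(1.0 / (NOISE_HOLD_HZ * dt))))
    n_draws = n_steps // hold + 1
    draws = rng.normal(0.0, sd, size=n_draws)
    return np.repeat(draws, hold)[:n_steps]


class Participant:
    """One surrogate with a fixed corrupted internal pendulum model.

    The perceived rod length and gravity are drawn once per participant
    (uniform within +/- 30 % * (1 - skill)), so a given surrogate is
    consistently wrong in the same way across a session, like a subject with
    a stable misperception of the dynamics.
    """

    def __init__(self, params: ParticipantParams,
                 pendulum: PendulumParams | None = None,
                 ee_model: EndEffectorModel | None = None):
        self.params = params
        self.pendulum = pendulum or PendulumParams()
        self.ee_model = ee_model or EndEffectorModel()
        rng = np.random.default_rng(params.rng_seed)
        bias = MODEL_BIAS_MAX * (1.0 - params.skill)
        self.perceived = PendulumParams(
            m=self.pendulum.m,
            l=self.pendulum.l * (1.0 + bias * rng.uniform(-1, 1)),
            g=self.pendulum.g * (1.0 + bias * rng.uniform(-1, 1)),
            c=self.pendulum.c,
        )
        self._intent_cfg = MpcConfig(
            force_limit=INTENT_FORCE_CAP,
            application_point=AssistPoint.END_EFFECTOR,
            sqp_iters=8,
        )

    def plan_intent(self, state: SimState, target: TargetSpec) -> Intent:
        """Desired end-effector path from now to the target impact.

        Runs the trajectory optimizer with the participant's *perceived*
        pendulum parameters and a human-scale effort cap; at skill 1 this is
        the ideal-participant plan on the true dynamics.
        """
        plan = mpc_plan(state, target, self._intent_cfg,
                        self.perceived, self.ee_model)
        return Intent(times=plan.times,
                      y=plan.predicted_states[:, 0].copy(),
                      y_dot=plan.predicted_states[:, 1].copy())

    def slack_factor(self, perceived_assist: float, assist_limit: float) -> float:
        """Multiplier on lateral hand effort given the perceived assist level."""
        if assist_limit <= 0:
            return 1.0
        frac = min(1.0, abs(perceived_assist) / assist_limit)
        return 1.0 - self.params.slack_gain * frac

    def effort_factor(self, perceived_assist: float, felt_at_hand: float,
                      assist_limit: float) -> float:
        """Net multiplier on the lateral tracking effort.

        Slacking (driven by how much the robot is seen to work, wherever its
        force acts) reduces the voluntary drive; impedance up-regulation
        (driven only by force actually felt at the hand, i.e. assistance
        applied at the end-effector) stiffens the arm against the
        perturbation.  Ball-applied assistance is barely felt at the hand,
        so it slackens without stiffening.
        """
        if assist_limit <= 0:
            return 1.0
        frac_seen = min(1.0, abs(perceived_assist) / assist_limit)
        frac_felt = min(1.0, abs(felt_at_hand) / assist_limit)
        f = (1.0 - self.params.slack_gain * frac_seen
             + self.params.stiffen_gain * frac_felt)
        return max(0.2, f)

    def hand_force(self, state: SimState, intent: Intent,
                   perceived_assist: float = 0.0,
                   assist_limit: float = 8.0,
                   noise: float = 0.0) -> tuple[float, float]:
        """Instantaneous hand force (F_y, F_z).

        Lateral: slacked PD tracking of the delayed intent reference plus
        motor noise.  Vertical: un-slacked PD about the home height.
        """
        p = self.params
        t_ref = state.t - p.reaction_delay
        e = float(intent.position(t_ref)) - state.y
        ed = float(intent.velocity(t_ref)) - state.y_dot
        slack = self.slack_factor(perceived_assist, assist_limit)
        f_y = slack * (p.hand_P * e + p.hand_D * ed + noise)
        f_z = p.z_P * (p.z_home - state.z) - p.z_D * state.z_dot
        return f_y, f_z
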