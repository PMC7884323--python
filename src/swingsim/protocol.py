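"""Session orchestration: block schedule, closed-loop execution, metrics.

A session follows the training-study structure: a 40-target baseline, a
1-minute transfer (pendulum inversion) baseline, 32 training blocks of 20
targets with 8 unannounced catch blocks (assistance silently off, half
before the mid-session break), a 20-target washout, a short-term retention
test, a transfer test, a long-term retention test and a final transfer
test.  Baseline and both retention tests reuse one identical target layout
built from two repetitions of the catch-block layout; training layouts
differ between blocks but depend only on the configured seeds, never on
simulation outcomes.

The long-term retention test is simulated as an immediate re-test: the
study's between-session consolidation gap has no simulated analogue (the
surrogates do not learn), and the block is labelled accordingly.  The
mid-session break is recorded as a no-op marker.
"""

from __future__ import annotations

import enum
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _core
from .assistance import (HgConfig, HgController, MpcConfig, MpcController,
                         NullController, hg_force)
from .dynamics import (AssistPoint, EndEffectorModel, PendulumParams, SimState,
                       natural_frequency)
from .logs import LOG_COLUMNS, TrialLog
from .metrics import block_metrics
from .participant import (Participant, ParticipantParams, motor_noise, preset)
from .task import (BlockKind, BlockSpec, TargetSpec, generate_targets,
                   transfer_score_from_series)

__all__ = ["Group", "ProtocolConfig", "build_schedule", "targets_for_block",
           "run_block", "run_session", "BlockResult", "SessionResult"]

SIM_DT = 1e-3  # s; fixed closed-loop integration step


class Group(enum.Enum):
    CONTROL = "control"
    EEMPC = "eeMPC"
    BALLMPC = "ballMPC"
    HG = "HG"


@dataclass(frozen=True)
class ProtocolConfig:
    """Schedule composition and seeding of one simulated session."""

    group: Group = Group.CONTROL
    n_training_blocks: int = 32
    n_catch: int = 8
    targets_per_training_block: int = 20
    baseline_targets: int = 40
    washout_targets: int = 20
    retention_targets: int = 40
    transfer_duration: float = 60.0
    interval: float = 1.0
    catch_placement_seed: int = 12345
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_catch > self.n_training_blocks or self.n_catch % 2:
            raise ValueError("need an even n_catch <= n_training_blocks")
        if self.n_training_blocks % 2:
            raise ValueError("training blocks must split evenly around the break")
        for n, per in ((self.baseline_targets, "baseline"),
                       (self.retention_targets, "retention")):
            if n % self.targets_per_training_block:
                raise ValueError(
                    f"{per} target count must be a multiple of the training "
                    "block size so the shared layout can be tiled")

    def _seed_seq(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.master_seed)

    def derived_seed(self, *key: int) -> int:
        ss = np.random.SeedSequence(self.master_seed, spawn_key=tuple(key))
        return int(ss.generate_state(1)[0] % (2 ** 31))


# fixed spawn-key namespaces for derived seeds
_K_CATCH_LAYOUT = 1
_K_TRAINING = 2
_K_WASHOUT = 3
_K_NOISE = 4
_K_PARTICIPANT = 5


def build_schedule(config: ProtocolConfig) -> list[BlockSpec]:
    """Ordered block list of one session.

    Catch positions are drawn from ``catch_placement_seed`` only — exactly
    half fall before the break — and are independent of the master seed, so
    the same placement serves every simulated participant.
    """
    assisted = config.group is not Group.CONTROL
    rng = np.random.default_rng(config.catch_placement_seed)
    half = config.n_training_blocks // 2
    first = rng.choice(half, size=config.n_catch // 2, replace=False)
    second = rng.choice(half, size=config.n_catch // 2, replace=False) + half
    catch_positions = set(first.tolist()) | set(second.tolist())

    blocks: list[BlockSpec] = []
    blocks.append(BlockSpec(kind=BlockKind.BASELINE,
                            n_targets=config.baseline_targets,
                            assistance_on=False,
                            rng_seed=config.derived_seed(_K_CATCH_LAYOUT),
                            label="baseline"))
    blocks.append(BlockSpec(kind=BlockKind.TRANSFER, n_targets=0,
                            assistance_on=False,
                            rng_seed=config.derived_seed(_K_CATCH_LAYOUT, 1),
                            duration=config.transfer_duration,
                            label="transfer-baseline"))
    for i in range(config.n_training_blocks):
        if i in catch_positions:
            blocks.append(BlockSpec(kind=BlockKind.CATCH,
                                    n_targets=config.targets_per_training_block,
                                    assistance_on=False,
                                    rng_seed=config.derived_seed(_K_CATCH_LAYOUT),
                                    label=f"catch-{i + 1:02d}"))
        else:
            blocks.append(BlockSpec(kind=BlockKind.TRAINING,
                                    n_targets=config.targets_per_training_block,
                                    assistance_on=assisted,
                                    rng_seed=config.derived_seed(_K_TRAINING, i),
                                    label=f"training-{i + 1:02d}"))
    blocks.append(BlockSpec(kind=BlockKind.WASHOUT,
                            n_targets=config.washout_targets,
                            assistance_on=False,
                            rng_seed=config.derived_seed(_K_WASHOUT),
                            label="washout"))
    for lab in ("STR", "LTR"):
        blocks.append(BlockSpec(kind=BlockKind.RETENTION,
                                n_targets=config.retention_targets,
                                assistance_on=False,
                                rng_seed=config.derived_seed(_K_CATCH_LAYOUT),
                                label=lab))
        blocks.append(BlockSpec(kind=BlockKind.TRANSFER, n_targets=0,
                                assistance_on=False,
                                rng_seed=config.derived_seed(_K_CATCH_LAYOUT, 1),
                                duration=config.transfer_duration,
                                label=f"transfer-{lab}"))
    return blocks


def targets_for_block(block: BlockSpec, config: ProtocolConfig) -> list[TargetSpec]:
    """Materialise the target sequence of a block from its seed.

    Baseline and retention blocks tile the 20-target catch layout twice,
    which makes their layouts element-wise identical to each other and to
    the catch blocks, as the protocol requires.
    """
    if block.kind is BlockKind.TRANSFER:
        return []
    base = generate_targets(config.targets_per_training_block,
                            interval=config.interval, rng_seed=block.rng_seed)
    if block.kind in (BlockKind.BASELINE, BlockKind.RETENTION):
        reps = block.n_targets // config.targets_per_training_block
        out: list[TargetSpec] = []
        for r in range(reps):
            for tg in base:
                out.append(replace(tg, index=tg.index + r * len(base),
                                   impact_time=tg.impact_time
                                   + r * len(base) * config.interval))
        return out
    return base[:block.n_targets]


def _make_controller(group: Group, block: BlockSpec,
                     params: PendulumParams, ee_model: EndEffectorModel,
                     ee_mpc: MpcConfig, ball_mpc: MpcConfig, hg: HgConfig):
    if not block.assistance_on or group is Group.CONTROL:
        return NullController(), None
    if group is Group.EEMPC:
        return MpcController(ee_mpc, params, ee_model), ee_mpc
    if group is Group.BALLMPC:
        return MpcController(ball_mpc, params, ee_model), ball_mpc
    if group is Group.HG:
        return HgController(hg, ee_mpc, params, ee_model), ee_mpc
    raise ValueError(group)


@dataclass
class BlockResult:
    """One executed block: its log, the per-target misses and audit info."""

    block: BlockSpec
    log: TrialLog
    targets: list[TargetSpec]
    miss_distances: np.ndarray        # m, |ball_y - target_y| at impact
    transfer_score: float = float("nan")
    hg_fit_counts: list[int] = field(default_factory=list)
    runtime_s: float = 0.0


_POINT_CODE = {AssistPoint.NONE: 0, AssistPoint.END_EFFECTOR: 1, AssistPoint.BALL: 2}


def run_block(block: BlockSpec,
              participant: Participant,
              group: Group = Group.CONTROL,
              config: ProtocolConfig | None = None,
              ee_mpc: MpcConfig | None = None,
              ball_mpc: MpcConfig | None = None,
              hg: HgConfig | None = None,
              noise_seed: int = 0,
              initial_state: SimState | None = None) -> BlockResult:
    """Execute one block closed-loop at 1 kHz and return its log.

    Per target: the participant plans an intent and the HG controller fits
    its (single) trajectory at the moment the previous target is passed; the
    MPC replans at its configured rate with the first-interval force
    zero-order held in between; hand PD tracking, motor noise and slacking
    act at the simulation rate inside the compiled kernel.
    """
    t_wall = time.perf_counter()
    config = config or ProtocolConfig(group=group)
    params = participant.pendulum
    ee_model = participant.ee_model
    ee_mpc = ee_mpc or MpcConfig.for_end_effector()
    ball_mpc = ball_mpc or MpcConfig.for_ball()
    hg = hg or HgConfig()
    pp = participant.params

    if block.kind is BlockKind.TRANSFER:
        return _run_transfer_block(block, participant, group, config,
                                   noise_seed, t_wall)

    targets = targets_for_block(block, config)
    duration = targets[-1].impact_time
    n_steps = int(round(duration / SIM_DT))
    nrow = n_steps + 1

    controller, active_cfg = _make_controller(group, block, params, ee_model,
                                              ee_mpc, ball_mpc, hg)
    point_code = _POINT_CODE[controller.application_point]
    assist_limit = active_cfg.force_limit if active_cfg is not None else (
        hg.force_limit if group is Group.HG else 8.0)
    replan_rate = active_cfg.replan_rate if active_cfg is not None else 80.0

    logs = {c: np.zeros(nrow) for c in LOG_COLUMNS
            if c not in ("assist_point", "t")}
    ref_y = np.zeros(nrow)
    ref_yd = np.zeros(nrow)
    hg_ref_y = np.zeros(nrow)
    hg_ref_yd = np.zeros(nrow)
    rng = np.random.default_rng(noise_seed)
    noise = motor_noise(nrow, SIM_DT, pp.noise_sd, rng)
    delay_steps = int(round(pp.reaction_delay / SIM_DT))
    is_hg = isinstance(controller, HgController)

    s = (initial_state or SimState()).to_array()
    i = 0
    hg_fit_counts = []
    for tg in targets:
        i_start = i
        i_end = int(round(tg.impact_time / SIM_DT))
        t_now = i * SIM_DT
        state = SimState.from_array(t_now, s)

        intent = participant.plan_intent(state, tg)
        sl = slice(i_start, i_end + 1)
        t_slice = np.arange(i_start, i_end + 1) * SIM_DT
        ref_y[sl] = intent.position(t_slice)
        ref_yd[sl] = intent.velocity(t_slice)

        controller.start_target(state, tg)
        if is_hg:
            traj = controller._trajectory
            hg_ref_y[sl] = traj.position(t_slice)
            hg_ref_yd[sl] = traj.velocity(t_slice)

        next_event = t_now
        while i < i_end:
            t_now = i * SIM_DT
            state = SimState.from_array(t_now, s)
            # gross tracking error: the surrogate re-plans from where it is
            if (abs(ref_y[i] - s[0]) > pp.replan_threshold
                    and tg.impact_time - t_now > 0.1):
                intent = participant.plan_intent(state, tg)
                sl2 = slice(i, i_end + 1)
                t_slice2 = np.arange(i, i_end + 1) * SIM_DT
                ref_y[sl2] = intent.position(t_slice2)
                ref_yd[sl2] = intent.velocity(t_slice2)
            if is_hg:
                assist_now = hg_force(state, traj, hg)
                assist_f = 0.0
                mode = 1
            else:
                assist_f = controller.update(state, tg) \
                    if not isinstance(controller, NullController) else 0.0
                assist_now = assist_f
                mode = 0
            felt_at_hand = assist_now if point_code == 1 else 0.0
            slack = participant.effort_factor(assist_now, felt_at_hand,
                                              assist_limit) \
                if block.assistance_on else 1.0

            next_event += 1.0 / replan_rate
            span = int(round(next_event / SIM_DT)) - i
            span = max(1, min(span, i_end - i))
            s = _core.run_span(
                s, i, span, SIM_DT, ref_y, ref_yd, delay_steps,
                pp.hand_P, pp.hand_D, pp.z_P, pp.z_D, pp.z_home,
                slack, noise,
                mode, assist_f, point_code,
                hg_ref_y, hg_ref_yd, hg.P_eff, hg.D_eff, hg.force_limit,
                params.m, params.l, params.g, params.c,
                ee_model.m_ee, ee_model.b_ee,
                logs["y"], logs["z"], logs["y_dot"], logs["z_dot"],
                logs["theta"], logs["theta_dot"],
                logs["F_hand_y"], logs["F_hand_z"], logs["F_assist_y"],
                logs["F_rod_y"], logs["F_rod_z"])
            i += span
        if is_hg:
            hg_fit_counts.append(controller.fit_count)

    # final sample: state at the last impact time, forces carried over
    for key, col in (("y", 0), ("z", 1), ("y_dot", 2), ("z_dot", 3),
                     ("theta", 4), ("theta_dot", 5)):
        logs[key][n_steps] = s[col]
    for key in ("F_hand_y", "F_hand_z", "F_assist_y", "F_rod_y", "F_rod_z"):
        logs[key][n_steps] = logs[key][n_steps - 1]

    frame = pd.DataFrame({"t": np.arange(nrow) * SIM_DT, **logs})
    frame["assist_point"] = controller.application_point.value
    frame = frame[LOG_COLUMNS]
    meta = {"group": group.value, "kind": block.kind.value,
            "label": block.label, "assistance_on": block.assistance_on}
    log = TrialLog(data=frame, params=params, ee_model=ee_model,
                   targets=targets, seed=noise_seed, meta=meta)

    ball_y = log.ball_y()
    t_arr = frame["t"].to_numpy()
    miss = np.array([abs(float(np.interp(tg.impact_time, t_arr, ball_y))
                         - tg.y_target) for tg in targets])
    fits = [hg_fit_counts[0]] + list(np.diff(hg_fit_counts)) if hg_fit_counts else []
    return BlockResult(block=block, log=log, targets=targets,
                       miss_distances=miss, hg_fit_counts=fits,
                       runtime_s=time.perf_counter() - t_wall)


# surrogate swing-up behaviour during the transfer (inversion) test
_TRANSFER_KE_BASE = 2.0    # N/J at skill 0
_TRANSFER_KE_SKILL = 14.0  # extra N/J at skill 1
_TRANSFER_KC = 20.0        # N/m workspace centering
_TRANSFER_KCD = 2.0        # N s/m (light, so centering does not kill pumping)
_TRANSFER_FMAX = 15.0      # N voluntary force cap


def _run_transfer_block(block: BlockSpec, participant: Participant,
                        group: Group, config: ProtocolConfig,
                        noise_seed: int, t_wall: float) -> BlockResult:
    params = participant.pendulum
    ee_model = participant.ee_model
    pp = participant.params
    n_steps = int(round(block.duration / SIM_DT))
    nrow = n_steps + 1
    logs = {c: np.zeros(nrow) for c in LOG_COLUMNS
            if c not in ("assist_point", "t")}
    rng = np.random.default_rng(noise_seed)
    noise = motor_noise(nrow, SIM_DT, pp.noise_sd, rng)
    ke = _TRANSFER_KE_BASE + _TRANSFER_KE_SKILL * pp.skill

    s = SimState().to_array()
    s = _core.run_transfer_span(
        s, 0, n_steps, SIM_DT,
        ke, _TRANSFER_KC, _TRANSFER_KCD, _TRANSFER_FMAX,
        pp.z_P, pp.z_D, pp.z_home, noise,
        params.m, params.l, params.g, params.c, ee_model.m_ee, ee_model.b_ee,
        logs["y"], logs["z"], logs["y_dot"], logs["z_dot"],
        logs["theta"], logs["theta_dot"],
        logs["F_hand_y"], logs["F_hand_z"], logs["F_assist_y"],
        logs["F_rod_y"], logs["F_rod_z"])
    for key, col in (("y", 0), ("z", 1), ("y_dot", 2), ("z_dot", 3),
                     ("theta", 4), ("theta_dot", 5)):
        logs[key][n_steps] = s[col]
    for key in ("F_hand_y", "F_hand_z", "F_assist_y", "F_rod_y", "F_rod_z"):
        logs[key][n_steps] = logs[key][n_steps - 1]

    frame = pd.DataFrame({"t": np.arange(nrow) * SIM_DT, **logs})
    frame["assist_point"] = AssistPoint.NONE.value
    frame = frame[LOG_COLUMNS]
    meta = {"group": group.value, "kind": block.kind.value,
            "label": block.label, "assistance_on": False}
    log = TrialLog(data=frame, params=params, ee_model=ee_model,
                   targets=[], seed=noise_seed, meta=meta)
    z_diff = log.ball_z() - frame["z"].to_numpy()
    score = transfer_score_from_series(z_diff, SIM_DT, k=1.0)
    return BlockResult(block=block, log=log, targets=[],
                       miss_distances=np.empty(0), transfer_score=score,
                       runtime_s=time.perf_counter() - t_wall)


@dataclass
class SessionResult:
    """All block results of one session plus the tidy metrics table."""

    config: ProtocolConfig
    results: list[BlockResult]
    metrics: pd.DataFrame


def run_session(config: ProtocolConfig,
                participant_params: ParticipantParams | str = "novice",
                params: PendulumParams | None = None,
                ee_model: EndEffectorModel | None = None,
                ee_mpc: MpcConfig | None = None,
                ball_mpc: MpcConfig | None = None,
                hg: HgConfig | None = None,
                schedule: list[BlockSpec] | None = None,
                keep_logs: bool = True) -> SessionResult:
    """Run a full session closed-loop; fully reproducible from the config seeds.

    Returns per-block results and one tidy metrics row per block (transfer
    blocks report the transfer score; target blocks the seven summary
    metrics).  ``keep_logs=False`` drops the full-rate logs after each block
    to bound memory on long sweeps.
    """
    params = params or PendulumParams()
    ee_model = ee_model or EndEffectorModel()
    if isinstance(participant_params, str):
        participant_params = preset(participant_params)
    participant_params = replace(
        participant_params, rng_seed=config.derived_seed(_K_PARTICIPANT))
    participant = Participant(participant_params, params, ee_model)
    schedule = schedule or build_schedule(config)
    wn = natural_frequency(params)

    rows = []
    results = []
    for order, block in enumerate(schedule):
        res = run_block(block, participant, config.group, config,
                        ee_mpc, ball_mpc, hg,
                        noise_seed=config.derived_seed(_K_NOISE, order))
        row = {"group": config.group.value, "kind": block.kind.value,
               "label": block.label, "order": order,
               "assistance_on": block.assistance_on,
               "seed": block.rng_seed, "transfer_score": res.transfer_score}
        if block.kind is not BlockKind.TRANSFER:
            row.update(block_metrics(res.log, res.targets, wn).as_dict())
        if not keep_logs:
            res.log = None
        results.append(res)
        rows.append(row)
    return SessionResult(config=config, results=results,
                         metrics=pd.DataFrame(rows))
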