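"""Target generation and scoring for the pendulum hitting and transfer tasks.

Targets appear on walls that approach the pendulum plane at constant speed,
one every second, at one of three lateral slots (centre, 12 cm left, 12 cm
right) with a small Gaussian positional jitter (sigma 1.25 cm).  The hit
score is a linear function of the lateral ball-to-target distance at the
moment of wall impact, clamped to [0, 100].

The transfer task asks the participant to invert the pendulum; its score
integrates ``k * z_diff`` over time whenever the ball is above the pivot and
is retained between inversions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Slot",
    "BlockKind",
    "TargetSpec",
    "BlockSpec",
    "TransferState",
    "generate_targets",
    "score_hit",
    "transfer_update",
    "transfer_score_from_series",
    "targets_to_frame",
    "targets_from_frame",
]

DEFAULT_SLOT_MEANS = (-0.12, 0.0, 0.12)  # m
DEFAULT_JITTER_SD = 0.0125               # m
DEFAULT_INTERVAL = 1.0                   # s
SCORE_PER_MM = 0.5                       # score points lost per mm of miss


class Slot(enum.Enum):
    LEFT = "left"
    CENTER = "center"
    RIGHT = "right"


_SLOT_ORDER = (Slot.LEFT, Slot.CENTER, Slot.RIGHT)


class BlockKind(enum.Enum):
    BASELINE = "baseline"
    TRAINING = "training"
    CATCH = "catch"
    WASHOUT = "washout"
    RETENTION = "retention"
    TRANSFER = "transfer"


@dataclass(frozen=True)
class TargetSpec:
    """One approaching target: lateral position and absolute impact time."""

    index: int
    slot: Slot
    y_target: float
    impact_time: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y_target) and math.isfinite(self.impact_time)):
            raise ValueError("target fields must be finite")


@dataclass(frozen=True)
class BlockSpec:
    """Composition of one block of the protocol."""

    kind: BlockKind
    n_targets: int
    assistance_on: bool
    rng_seed: int
    duration: float | None = None  # s, transfer blocks only
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind is BlockKind.TRANSFER:
            if self.n_targets != 0:
                raise ValueError("transfer blocks have no targets")
            if not (self.duration and self.duration > 0):
                raise ValueError("transfer blocks need a positive duration")
        elif self.n_targets < 1:
            raise ValueError("non-transfer blocks need at least one target")
        if self.kind is BlockKind.CATCH and self.assistance_on:
            raise ValueError("catch blocks are by definition unassisted")


def generate_targets(n: int,
                     slot_means: Sequence[float] = DEFAULT_SLOT_MEANS,
                     jitter_sd: float = DEFAULT_JITTER_SD,
                     interval: float = DEFAULT_INTERVAL,
                     rng_seed: int = 0) -> list[TargetSpec]:
    """Draw a target sequence: uniform slot choice plus Gaussian jitter.

    Impact times are ``interval, 2*interval, ...`` (the first wall arrives
    one interval after the block starts).  Deterministic given ``rng_seed``.
    """
    if n < 1:
        raise ValueError("need at least one target")
    if len(slot_means) == 0:
        raise ValueError("slot_means must be non-empty")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    slots = rng.integers(0, len(slot_means), size=n)
    jitter = rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n)
    out = []
    for i in range(n):
        slot = _SLOT_ORDER[slots[i]] if len(slot_means) == 3 else Slot.CENTER
        out.append(TargetSpec(index=i, slot=slot,
                              y_target=float(slot_means[slots[i]] + jitter[i]),
                              impact_time=float((i + 1) * interval)))
    return out


def score_hit(ball_y: float, target_y: float) -> float:
    """Hit score in [0, 100]: 100 minus half a point per millimetre of miss."""
    if not (math.isfinite(ball_y) and math.isfinite(target_y)):
        raise ValueError("positions must be finite")
    distance_mm = abs(ball_y - target_y) * 1000.0
    return float(min(100.0, max(0.0, 100.0 - distance_mm * SCORE_PER_MM)))


@dataclass(frozen=True)
class TransferState:
    """Accumulated transfer score and inversion bookkeeping."""

    score: float = 0.0
    k: float = 1.0
    inverted: bool = False
    z_diff: float = 0.0


def transfer_update(state: TransferState, z_diff: float, dt: float) -> TransferState:
    """Accumulate ``k * z_diff * dt`` while the ball is above the pivot.

    The score is retained (never decremented) when the pendulum falls; the
    ``inverted`` flag tracks the sign of ``z_diff``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    score = state.score
    if z_diff > 0:
        score += state.k * z_diff * dt
    return replace(state, score=score, inverted=z_diff > 0, z_diff=z_diff)


def transfer_score_from_series(z_diff: np.ndarray, dt: float, k: float = 1.0) -> float:
    """Transfer score of a whole logged test (vectorised transfer_update)."""
    z = np.asarray(z_diff, dtype=float)
    return float(k * dt * z[z > 0].sum())


def targets_to_frame(targets: Sequence[TargetSpec]) -> pd.DataFrame:
    return pd.DataFrame({
        "index": [t.index for t in targets],
        "slot": [t.slot.value for t in targets],
        "y_target": [t.y_target for t in targets],
        "impact_time": [t.impact_time for t in targets],
    })


def targets_from_frame(frame: pd.DataFrame) -> list[TargetSpec]:
    return [TargetSpec(index=int(r["index"]), slot=Slot(r["slot"]),
                       y_target=float(r["y_target"]),
                       impact_time=float(r["impact_time"]))
            for _, r in frame.iterrows()]
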