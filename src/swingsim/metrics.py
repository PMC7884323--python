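"""Per-block performance metrics.

Seven summary metrics per block: mean and standard deviation of the hit
score, percentage of the pendulum angle's spectral power within a narrow
band around the natural frequency, standard deviations of the end-effector
lateral position and of the pendulum angle, mean absolute assisting force,
and mean absolute human-robot interaction force.

The spectral fraction uses a Hann-window periodogram of the mean-removed
angle: the band half-width (0.05 Hz) equals the DFT bin width of the
shortest (20 s) block, and the Hann window keeps the leakage of
off-bin oscillations concentrated so that band fractions are meaningful at
that resolution.  Standard deviations use the population (n) convention.

The interaction force is estimated with a first-order disturbance observer
on the lateral admittance model — the simulation-side analogue of a
reaction-torque observer: the hand force is whatever residual effort
explains the observed end-effector acceleration after accounting for
damping, the rendered rod force and any assist applied at the end-effector,
low-pass filtered at 20 Hz.  In simulation the true hand force is logged,
so the observer can be validated against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .dynamics import EndEffectorModel
from .logs import TrialLog
from .task import TargetSpec, score_hit

__all__ = ["BlockMetrics", "psd_percent_around_wn", "block_metrics",
           "estimate_interaction_force", "scores_at_impacts"]

DEFAULT_HALFBAND = 0.05      # Hz
DEFAULT_OBSERVER_CUTOFF = 20.0  # Hz


@dataclass(frozen=True)
class BlockMetrics:
    """The seven per-block summary metrics."""

    mean_score: float
    std_score: float
    psd_pct_wn: float
    std_ee_pos: float
    std_theta: float
    mean_abs_assist: float
    mean_abs_interaction: float

    def as_dict(self) -> dict:
        return asdict(self)


def psd_percent_around_wn(theta: np.ndarray, fs: float, wn: float,
                          halfband: float = DEFAULT_HALFBAND,
                          window: str = "hann") -> float:
    """Percentage of spectral power within ``wn +/- halfband`` Hz.

    Periodogram of the mean-removed series (Hann window by default, which
    keeps leakage of tones that fall between DFT bins inside the band);
    band edges inclusive.  A constant series has no oscillatory power and
    returns 0 with a warning.
    """
    x = np.asarray(theta, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        warnings.warn("constant angle series: no oscillatory power, "
                      "PSD fraction defined as 0%", stacklevel=2)
        return 0.0
    freqs, pxx = signal.periodogram(x, fs=fs, window=window, detrend=False)
    band = (freqs >= wn - halfband) & (freqs <= wn + halfband)
    return float(100.0 * pxx[band].sum() / pxx.sum())


def scores_at_impacts(log: TrialLog, targets: list[TargetSpec]) -> np.ndarray:
    """Per-target hit scores, sampling the ball at each impact time.

    The lateral ball position is linearly interpolated at the exact impact
    time.  A target whose impact time lies outside the logged span raises an
    error naming the target index.
    """
    t = log.data["t"].to_numpy()
    ball_y = log.ball_y()
    scores = np.empty(len(targets))
    for i, tg in enumerate(targets):
        if tg.impact_time < t[0] - 1e-9 or tg.impact_time > t[-1] + 1e-9:
            raise ValueError(
                f"log does not cover impact of target {tg.index} "
                f"(t={tg.impact_time}, log spans [{t[0]}, {t[-1]}])")
        by = float(np.interp(tg.impact_time, t, ball_y))
        scores[i] = score_hit(by, tg.y_target)
    return scores


def estimate_interaction_force(log: TrialLog,
                               ee_model: EndEffectorModel | None = None,
                               cutoff_hz: float = DEFAULT_OBSERVER_CUTOFF) -> np.ndarray:
    """Disturbance-observer estimate of the lateral hand force time series.

    F_hat = LPF( m_ee * y_ddot + b_ee * y_dot - F_rod_y - F_assist_ee ),
    with the acceleration differenced from the logged velocity and a causal
    second-order Butterworth low-pass at ``cutoff_hz``.
    """
    ee = ee_model or log.ee_model
    t = log.data["t"].to_numpy()
    y_dot = log.data["y_dot"].to_numpy()
    y_ddot = np.gradient(y_dot, t)
    raw = (ee.m_ee * y_ddot + ee.b_ee * y_dot
           - log.data["F_rod_y"].to_numpy()
           - log.assist_at_end_effector())
    fs = 1.0 / log.dt
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    return signal.sosfilt(sos, raw)


def block_metrics(log: TrialLog, targets: list[TargetSpec], wn: float,
                  halfband: float = DEFAULT_HALFBAND) -> BlockMetrics:
    """All seven summary metrics of one block."""
    scores = scores_at_impacts(log, targets)
    theta = log.data["theta"].to_numpy()
    fs = 1.0 / log.dt
    interaction = estimate_interaction_force(log)
    return BlockMetrics(
        mean_score=float(scores.mean()),
        std_score=float(scores.std()),          # population convention
        psd_pct_wn=psd_percent_around_wn(theta, fs, wn, halfband),
        std_ee_pos=float(log.data["y"].to_numpy().std()),
        std_theta=float(theta.std()),
        mean_abs_assist=float(np.abs(log.data["F_assist_y"].to_numpy()).mean()),
        mean_abs_interaction=float(np.abs(interaction).mean()),
    )
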