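"""Per-block metric suite: PSD band fraction, score stats, force observer."""

import numpy as np
import pandas as pd
import pytest

from swingsim import _core
from swingsim.dynamics import (AssistPoint, EndEffectorModel, PendulumParams,
                               natural_frequency)
from swingsim.logs import LOG_COLUMNS, TrialLog
from swingsim.metrics import (block_metrics, estimate_interaction_force,
                              psd_percent_around_wn, scores_at_impacts)
from swingsim.task import Slot, TargetSpec

FS = 1000.0


def _make_log(n, params=None, ee_model=None, **columns):
    params = params or PendulumParams()
    ee_model = ee_model or EndEffectorModel()
    data = {c: np.zeros(n) for c in LOG_COLUMNS if c != "assist_point"}
    data["t"] = np.arange(n) / FS
    data.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    frame = pd.DataFrame(data)
    frame["assist_point"] = AssistPoint.NONE.value
    return TrialLog(data=frame[LOG_COLUMNS], params=params, ee_model=ee_model)


class TestPsdFraction:
    def test_pure_tone_in_band(self):
        # record long enough that the window mainlobe sits inside the band
        t = np.arange(int(100 * FS)) / FS
        x = np.sin(2 * np.pi * 0.57 * t)
        assert psd_percent_around_wn(x, FS, 0.57) >= 99.0

    def test_pure_tone_out_of_band(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.50 * t)
        assert psd_percent_around_wn(x, FS, 0.57) <= 1.0

    def test_two_resolved_tones_split_evenly(self):
        # equal-amplitude tones at 0.57 and 1.50 Hz over 40 s: Parseval
        # splits the power evenly between the two resolved lines
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 0.57 * t) + np.sin(2 * np.pi * 1.50 * t + 0.3)
        assert psd_percent_around_wn(x, FS, 0.57) == pytest.approx(50.0, abs=2.0)

    def test_amplitude_and_offset_invariance(self, rng):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 0.6 * t) + 0.3 * rng.normal(size=t.size)
        base = psd_percent_around_wn(x, FS, 0.57)
        assert psd_percent_around_wn(5.0 * x, FS, 0.57) == pytest.approx(base)
        assert psd_percent_around_wn(x + 2.0, FS, 0.57) == pytest.approx(base)

    def test_complementary_bands_partition_power(self, rng):
        # non-overlapping bands tiling (0, fs/2], with edges placed between
        # DFT bins so no bin is counted twice: fractions must sum to 100
        x = rng.normal(size=int(20 * FS))
        edges = np.linspace(0.0, FS / 2, 6) - 0.025
        edges[-1] = FS / 2 + 0.025  # include DC and Nyquist bins
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            centre, half = (lo + hi) / 2, (hi - lo) / 2
            total += psd_percent_around_wn(x, FS, centre, halfband=half)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_twenty_second_block_resolution_is_fifty_mhz(self):
        """The shortest block (20 targets, 1 s spacing) has exactly the
        0.05 Hz bin width that motivates the band half-width."""
        from scipy.signal import periodogram
        n = int(20 * FS)
        freqs, _ = periodogram(np.random.default_rng(0).normal(size=n), fs=FS,
                               window="boxcar")
        assert freqs[1] - freqs[0] == pytest.approx(0.05)

    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert psd_percent_around_wn(np.ones(2000), FS, 0.57) == 0.0


class TestBlockMetrics:
    def _targets(self, ys, interval=1.0):
        return [TargetSpec(i, Slot.CENTER, y, (i + 1) * interval)
                for i, y in enumerate(ys)]

    def test_perfect_hits(self):
        n = int(3 * FS) + 1
        log = _make_log(n, y=np.full(n, 0.05))
        m = block_metrics(log, self._targets([0.05] * 3),
                          natural_frequency(PendulumParams()))
        assert m.mean_score == 100.0
        assert m.std_score == 0.0
        assert m.std_ee_pos == pytest.approx(0.0, abs=1e-12)

    def test_prescribed_miss_distances(self):
        # misses of 0, 100 and 200 mm give scores 100, 50 and 0:
        # mean 50, population std sqrt(5000/3)
        n = int(3 * FS) + 1
        t = np.arange(n) / FS
        y = np.zeros(n)
        for i, miss in enumerate((0.0, 0.1, 0.2)):
            y[np.abs(t - (i + 1)) < 0.5e-3] = miss
        log = _make_log(n, y=y)
        m = block_metrics(log, self._targets([0.0] * 3),
                          natural_frequency(PendulumParams()))
        assert m.mean_score == pytest.approx(50.0)
        assert m.std_score == pytest.approx(np.sqrt(5000.0 / 3.0))

    def test_std_invariant_to_time_reversal(self, rng):
        n = int(5 * FS) + 1
        y = rng.normal(0, 0.05, size=n)
        theta = rng.normal(0, 0.3, size=n)
        fwd = _make_log(n, y=y, theta=theta)
        rev = _make_log(n, y=y[::-1], theta=theta[::-1])
        wn = natural_frequency(PendulumParams())
        targets = self._targets([0.0] * 5)
        mf, mr = block_metrics(fwd, targets, wn), block_metrics(rev, targets, wn)
        assert mf.std_ee_pos == pytest.approx(mr.std_ee_pos)
        assert mf.std_theta == pytest.approx(mr.std_theta)

    def test_missing_impact_coverage_names_target(self):
        log = _make_log(int(1.5 * FS))
        with pytest.raises(ValueError, match="target 1"):
            scores_at_impacts(log, self._targets([0.0, 0.0]))


def _simulate_constant_hand_force(f_hand, duration=4.0, noise_sd=0.0, seed=0):
    """Closed 6-state sim with a constant lateral hand force; full log."""
    p = PendulumParams()
    ee = EndEffectorModel()
    n = int(duration * FS)
    rng = np.random.default_rng(seed)
    cols = {c: np.zeros(n) for c in LOG_COLUMNS if c != "assist_point"}
    s = np.zeros(6)
    for i in range(n):
        fhy = f_hand + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        fhz = 200.0 * (0.0 - s[1]) - 20.0 * s[3]
        _, _, _, f_rod = _core.accels(*s, fhy, fhz, 0.0, p.m, p.l, p.g, p.c,
                                      ee.m_ee, ee.b_ee, False)
        cols["t"][i] = i / FS
        cols["y"][i], cols["z"][i] = s[0], s[1]
        cols["y_dot"][i], cols["z_dot"][i] = s[2], s[3]
        cols["theta"][i], cols["theta_dot"][i] = s[4], s[5]
        cols["F_hand_y"][i], cols["F_hand_z"][i] = fhy, fhz
        cols["F_rod_y"][i] = f_rod * np.sin(s[4])
        cols["F_rod_z"][i] = -f_rod * np.cos(s[4])
        s = _core.rk4_step(s, fhy, fhz, 0.0, 1e-3, p.m, p.l, p.g, p.c,
                           ee.m_ee, ee.b_ee, False)
    frame = pd.DataFrame(cols)
    frame["assist_point"] = AssistPoint.NONE.value
    return TrialLog(data=frame[LOG_COLUMNS], params=p, ee_model=ee)


class TestInteractionForceObserver:
    def test_recovers_constant_hand_force(self):
        log = _simulate_constant_hand_force(2.0)
        est = estimate_interaction_force(log)
        settled = est[int(1.0 * FS):]
        assert settled.mean() == pytest.approx(2.0, abs=0.1)

    def test_null_case(self):
        log = _simulate_constant_hand_force(0.0)
        est = estimate_interaction_force(log)
        assert np.sqrt(np.mean(est ** 2)) < 0.1

    def test_tracks_true_force_within_five_percent_rms(self):
        log = _simulate_constant_hand_force(1.0, noise_sd=0.0)
        est = estimate_interaction_force(log)
        truth = log.data["F_hand_y"].to_numpy()
        settled = slice(int(0.5 * FS), None)
        err = np.sqrt(np.mean((est[settled] - truth[settled]) ** 2))
        ref = np.sqrt(np.mean(truth[settled] ** 2))
        assert err / ref < 0.05
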