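"""Saccade detection: thresholding, merging, calibration, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eogscreen import (
    CalibrationConstants,
    EmptyInputError,
    EOGRecording,
    SaccadeDetectorConfig,
    calibrate_threshold,
    detect_saccades,
)
from eogscreen.detection import threshold_from_noise
from eogscreen.model import ConfigError

from conftest import brute_force_detect

CFG = SaccadeDetectorConfig(threshold_uV_per_ms=1.0)


def step_derivative(step_times, n=5000, width=10, peak=3.0):
    """Derivative trace of ideal amplitude steps: rectangular pulses."""
    d = np.zeros(n)
    for t in step_times:
        d[t : t + width] = peak
    return d


class TestDetectSaccades:
    def test_zero_derivative_no_events(self):
        assert detect_saccades(np.zeros(1000), CFG) == []

    def test_four_ideal_steps_four_events(self):
        times = [500, 1500, 2500, 3500]
        events = detect_saccades(step_derivative(times), CFG)
        assert len(events) == 4
        assert [ev.onset_ms for ev in events] == [float(t) for t in times]

    def test_runs_within_refractory_merge_to_one(self):
        d = np.zeros(500)
        d[100:110] = 2.0
        d[120:130] = 2.0  # 10 ms gap < 50 ms refractory
        events = detect_saccades(d, CFG)
        assert len(events) == 1
        assert events[0].onset_ms == 100.0
        assert events[0].offset_ms == 129.0

    def test_runs_beyond_refractory_stay_separate(self):
        d = np.zeros(500)
        d[100:110] = 2.0
        d[200:210] = 2.0
        assert len(detect_saccades(d, CFG)) == 2

    def test_short_runs_discarded(self):
        d = np.zeros(500)
        d[100:102] = 5.0  # 2 ms < 3 ms minimum
        assert detect_saccades(d, CFG) == []

    def test_negative_saccades_need_absolute_mode(self):
        d = step_derivative([100], peak=-3.0)
        assert len(detect_saccades(d, CFG)) == 1
        one_sided = SaccadeDetectorConfig(threshold_uV_per_ms=1.0, use_absolute=False)
        assert detect_saccades(d, one_sided) == []

    def test_event_fields_consistent(self):
        d = np.zeros(500)
        d[100:120] = np.linspace(1.0, 3.0, 20)
        (ev,) = detect_saccades(d, CFG)
        assert ev.onset_ms <= ev.peak_time_ms <= ev.offset_ms
        assert abs(ev.peak_derivative_uV_per_ms) >= CFG.threshold_uV_per_ms
        assert ev.direction == 1

    def test_empty_series_rejected(self):
        with pytest.raises(EmptyInputError):
            detect_saccades(np.array([]), CFG)

    def test_unset_threshold_rejected(self):
        cfg = SaccadeDetectorConfig(threshold_uV_per_ms=None)
        with pytest.raises(ConfigError):
            detect_saccades(np.zeros(10), cfg)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 0.6, 5000)
        for t in rng.integers(0, 4950, 8):
            d[t : t + rng.integers(2, 30)] += rng.choice([-1, 1]) * 2.5
        events = detect_saccades(d, CFG)
        oracle = brute_force_detect(
            d, CFG.threshold_uV_per_ms, CFG.refractory_ms, CFG.min_duration_ms
        )
        assert len(events) == len(oracle)
        for ev, (s, e, pk, pv) in zip(events, oracle):
            assert ev.onset_ms == float(s)
            assert ev.offset_ms == float(e)
            assert ev.peak_time_ms == float(pk)
            assert ev.peak_derivative_uV_per_ms == pytest.approx(pv)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.3, 3.0))
    def test_raising_threshold_never_adds_events(self, seed, th):
        """Monotone on saccade-like traces: unimodal pulses farther apart
        than the refractory gap (the regime ROS counting assumes)."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 0.05, 2000)
        kernel = np.exp(-0.5 * ((np.arange(25) - 12) / 4.0) ** 2)
        for t in range(100, 1900, 200):
            d[t : t + 25] += float(rng.uniform(0.2, 4.0)) * kernel
        lo = detect_saccades(d, SaccadeDetectorConfig(threshold_uV_per_ms=th))
        hi = detect_saccades(d, SaccadeDetectorConfig(threshold_uV_per_ms=th * 1.5))
        assert len(hi) <= len(lo)

    def test_subthreshold_noise_does_not_change_count(self):
        rng = np.random.default_rng(4)
        clean = step_derivative([500, 1500, 2500], peak=3.0)
        noise = rng.uniform(-0.4, 0.4, clean.size)  # stays below Th=1 margin
        assert len(detect_saccades(clean + noise, CFG)) == len(
            detect_saccades(clean, CFG)
        )


class TestCalibrateThreshold:
    def test_noise_floor_matches_folded_normal_statistics(self):
        """mean + 5·SD of |N(0, 0.1)| is 0.1·√(2/π) + 0.5·√(1−2/π) ≈ 0.3806."""
        rng = np.random.default_rng(0)
        # increments chosen so the central difference is marginally N(0, 0.1)
        steps = rng.normal(0, 0.1 * np.sqrt(2), 200_000)
        rec = EOGRecording(np.cumsum(steps))
        cfg = calibrate_threshold(
            [rec], k=5.0, filter_spec=None, velocity_floor_deg_per_s=0.0
        )
        assert cfg.threshold_uV_per_ms == pytest.approx(0.38064, abs=0.01)

    def test_threshold_from_noise_frozen_value(self):
        rng = np.random.default_rng(1)
        sample = np.abs(rng.normal(0, 0.1, 500_000))
        assert threshold_from_noise(sample, 5.0) == pytest.approx(0.38064, abs=0.005)

    def test_constant_recordings_fall_back_to_velocity_floor(self):
        rec = EOGRecording(np.full(1000, 10.0))
        with pytest.warns(UserWarning, match="constant"):
            cfg = calibrate_threshold([rec], filter_spec=None)
        assert cfg.threshold_uV_per_ms == pytest.approx(0.48)  # 30°/s × 16 µV/°

    def test_doubling_amplitudes_doubles_threshold(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(0, 0.2, 20_000))
        a = calibrate_threshold(
            [EOGRecording(x)], filter_spec=None, velocity_floor_deg_per_s=0.0
        )
        b = calibrate_threshold(
            [EOGRecording(2 * x)], filter_spec=None, velocity_floor_deg_per_s=0.0
        )
        assert b.threshold_uV_per_ms == pytest.approx(2 * a.threshold_uV_per_ms)

    def test_empty_recording_list_rejected(self):
        with pytest.raises(EmptyInputError):
            calibrate_threshold([])

    def test_vertical_calibration_scales_floor(self):
        rec = EOGRecording(np.full(1000, 0.0))
        with pytest.warns(UserWarning):
            cfg = calibrate_threshold(
                [rec], cal=CalibrationConstants.vertical(), filter_spec=None
            )
        assert cfg.threshold_uV_per_ms == pytest.approx(0.42)  # 30°/s × 14 µV/°
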