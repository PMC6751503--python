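"""Feature extraction: ROS, gaze deviation, response delay, full pipeline."""

import math

import numpy as np
import pytest

from eogscreen import (
    NO_RESPONSE,
    CalibrationConstants,
    SaccadeEvent,
    StimulusProtocol,
    SubjectProfile,
    compute_delay,
    compute_deviation,
    compute_ros,
    estimate_gaze_angle,
    extract_features,
    generate_recording,
)
from eogscreen.model import ConfigError


def make_event(onset_ms, peak=2.0):
    return SaccadeEvent(
        onset_ms=onset_ms,
        offset_ms=onset_ms + 30.0,
        peak_derivative_uV_per_ms=peak,
        peak_time_ms=onset_ms + 15.0,
        direction=1,
    )


class TestComputeRos:
    @pytest.mark.parametrize(
        "n,t,want", [(6, 45, 0.13), (0, 45, 0.0), (9, 45, 0.20), (4, 45, 0.09)]
    )
    def test_rounded_rate(self, n, t, want):
        assert compute_ros(n, t) == pytest.approx(want)

    def test_unrounded_quotient_times_t_recovers_n(self):
        for n in range(0, 12):
            assert compute_ros(n, 45.0, ndigits=None) * 45.0 == pytest.approx(n)

    def test_invalid_duration(self):
        with pytest.raises(ConfigError):
            compute_ros(3, 0.0)


class TestGazeAngle:
    def test_unit_cases(self, cal):
        assert estimate_gaze_angle(0.0, cal).degrees == 0.0
        assert estimate_gaze_angle(16.0, cal).degrees == pytest.approx(1.0)

    def test_reference_subject_inversion(self, cal):
        est = estimate_gaze_angle(336.48, cal)
        assert est.degrees == pytest.approx(21.03)
        assert est.in_linear_range

    def test_out_of_linear_range_flagged_not_raised(self, cal):
        est = estimate_gaze_angle(16.0 * 60.0, cal)
        assert est.degrees == pytest.approx(60.0)
        assert not est.in_linear_range


class TestComputeDeviation:
    def test_constant_static_amplitude(self, make_recording, protocol, cal):
        rec = make_recording(np.full(6000, 48.0))
        res = compute_deviation(rec, protocol, cal)
        assert res.deviation_deg == pytest.approx(3.0)

    def test_zero_signal_yields_minus_theta(self, make_recording, cal):
        proto = StimulusProtocol(theta_deg=2.0)
        res = compute_deviation(make_recording(np.zeros(6000)), proto, cal)
        assert res.deviation_deg == pytest.approx(-2.0)

    def test_offset_equivariance(self, make_recording, protocol, cal):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, 6000)
        base = compute_deviation(make_recording(x), protocol, cal)
        shifted = compute_deviation(make_recording(x + 32.0), protocol, cal)
        assert shifted.deviation_deg - base.deviation_deg == pytest.approx(2.0, abs=1e-9)

    def test_settle_must_fit_static_window(self, make_recording, protocol, cal):
        with pytest.raises(ConfigError):
            compute_deviation(
                make_recording(np.zeros(6000)), protocol, cal, settle_ms=6000.0
            )

    def test_simulated_deviation_recovered(self, protocol, cal):
        rec, _ = generate_recording(
            SubjectProfile(deviation_deg=2.0, seed=1), protocol, cal
        )
        res = compute_deviation(rec, protocol, cal)
        assert res.deviation_deg == pytest.approx(2.0, abs=0.2)


class TestComputeDelay:
    def test_delay_counts_samples_from_motion_onset(self, protocol):
        res = compute_delay([make_event(5156.0)], protocol)
        assert res.delay_ms == pytest.approx(156.0)
        assert res.n_samples == 156

    def test_event_at_onset_gives_zero(self, protocol):
        assert compute_delay([make_event(5000.0)], protocol).delay_ms == 0.0

    def test_no_event_after_onset_is_no_response(self, protocol):
        res = compute_delay([make_event(1000.0)], protocol)
        assert res.delay_ms == NO_RESPONSE
        assert res.n_samples is None
        assert not res.responded

    def test_mean_mode_averages_over_onsets(self, protocol):
        events = [make_event(o + 150.0) for o in protocol.motion_onsets_ms]
        res = compute_delay(events, protocol, mode="mean")
        assert res.delay_ms == pytest.approx(150.0)

    def test_amplitude_scaling_invariance(self, protocol):
        """Delay depends only on event timing, so amplitude-scaled events
        (same times, larger peaks) give the same answer."""
        a = compute_delay([make_event(5200.0, peak=2.0)], protocol)
        b = compute_delay([make_event(5200.0, peak=20.0)], protocol)
        assert a.delay_ms == b.delay_ms


class TestExtractFeatures:
    def test_recovery_on_clean_simulated_subject(self, protocol, cal):
        prof = SubjectProfile(
            n_extra_saccades=0, deviation_deg=0.0, latency_ms=150.0,
            noise_uV_rms=0.5, micromovement_amplitude_deg=0.3, seed=2,
        )
        rec, truth = generate_recording(prof, protocol, cal)
        fs = extract_features(rec, protocol, cal)
        assert fs.n_saccades == truth.n_events
        assert abs(fs.deviation_deg) < 0.5
        assert fs.delay_ms == pytest.approx(150.0, abs=10.0)
        assert fs.ros == compute_ros(fs.n_saccades, protocol.test_duration_s)

    def test_zero_signal_features(self, make_recording, protocol, cal):
        rec = make_recording(np.zeros(45001))
        fs = extract_features(rec, protocol, cal)
        assert fs.n_saccades == 0
        assert fs.ros == 0.0
        assert fs.deviation_deg == pytest.approx(-protocol.theta_deg)
        assert math.isinf(fs.delay_ms)

    def test_deterministic_across_runs(self, protocol, cal):
        rec, _ = generate_recording(SubjectProfile(seed=3, n_extra_saccades=2))
        a = extract_features(rec, protocol, cal)
        b = extract_features(rec, protocol, cal)
        assert a == b

    def test_randomized_parameter_recovery(self, protocol, cal):
        """Recover ground truth on a handful of randomized subjects; the
        20-recording sweep lives in the acceptance suite."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            prof = SubjectProfile(
                n_extra_saccades=int(rng.integers(0, 11)),
                deviation_deg=float(rng.uniform(-5, 5)),
                latency_ms=float(rng.uniform(100, 400)),
                seed=int(rng.integers(2**31)),
            )
            rec, truth = generate_recording(prof, protocol, cal)
            fs = extract_features(rec, protocol, cal)
            assert fs.n_saccades == truth.n_events
            assert fs.deviation_deg == pytest.approx(truth.deviation_deg, abs=0.3)
            assert fs.delay_ms == pytest.approx(truth.latency_ms, abs=15.0)
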