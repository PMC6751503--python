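"""Synthetic EOG generator with ground-truth annotations.

No raw recordings were published with the screening method, so this module
synthesises horizontal-channel EOG traces with the statistical structure
the real signals exhibit, driven by the same stimulus protocol the test
uses. Every generated trace carries an annotation of its true saccade
times, deviation and latency, so each pipeline stage — and the pipeline end
to end — can be validated by parameter recovery.

Signal model (angles in degrees, converted to µV through the dipole
sensitivity S):

* the stimulus angle θ(t) is static for 5 s, then a constant-speed
  triangular sweep with four direction changes at ±excursion;
* the eye tracks θ with smooth pursuit whose velocity matches the stimulus
  velocity delayed by the subject's latency, scaled by ``pursuit_gain``;
* at each motion onset (motion start and each direction change), the
  accumulated position error is closed by a catch-up saccade ``latency_ms``
  after the onset — saccades are raised-cosine transitions whose duration
  follows a main-sequence-like rule (≈21 ms + 2.2 ms/°), so a 10° saccade
  lasts ≈43 ms;
* involuntary extra saccades (the hallmark of poor fixation in ataxia) are
  rapid flicks away from the tracking trace with a slow sub-threshold glide
  back;
* fixational micromovements (drifts and flicks of ~1° amplitude) are a
  band-limited (≤2 Hz) zero-mean Gaussian process;
* slow electrode/corneo-retinal drift is linear in time; broadband noise is
  white Gaussian; optional blinks are asymmetric positive pulses (off by
  default for the horizontal montage, which largely suppresses them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as sps

from .model import (
    CalibrationConstants,
    ConfigError,
    EOGRecording,
    StimulusProtocol,
)

__all__ = [
    "SubjectProfile",
    "TrueEvent",
    "GroundTruth",
    "CohortMember",
    "stimulus_angle",
    "generate_recording",
    "generate_cohort",
    "healthy_profile",
    "ataxic_profile",
]

#: Smallest catch-up error (degrees) that triggers a modelled saccade;
#: smaller errors are corrected by pursuit alone.
MIN_SACCADE_DEG = 0.3


def _saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence-like duration: ~21 ms intercept + 2.2 ms per degree."""
    return 21.0 + 2.2 * abs(amplitude_deg)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative ground truth for one simulated subject.

    ``n_extra_saccades`` — involuntary saccades injected during tracking.
    ``deviation_deg`` — true fixation offset from the static stimulus.
    ``latency_ms`` — true saccadic reaction time to stimulus motion.
    ``pursuit_gain`` — fraction of stimulus velocity matched by pursuit.
    ``micromovement_amplitude_deg`` — typical peak excursion of fixational
    drift/flick activity (~1° physiologically); the band-limited process is
    scaled to a standard deviation of one third of this value.
    """

    n_extra_saccades: int = 0
    deviation_deg: float = 0.0
    latency_ms: float = 150.0
    pursuit_gain: float = 1.0
    blink_rate_hz: float = 0.0
    micromovement_amplitude_deg: float = 1.0
    noise_uV_rms: float = 2.0
    drift_uV_per_s: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_extra_saccades < 0:
            raise ConfigError("n_extra_saccades must be >= 0")
        if self.latency_ms < 0:
            raise ConfigError("latency_ms must be >= 0")
        if not (0.0 <= self.pursuit_gain <= 1.2):
            raise ConfigError("pursuit_gain must lie in [0, 1.2]")
        if self.micromovement_amplitude_deg < 0 or self.noise_uV_rms < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.blink_rate_hz < 0:
            raise ConfigError("blink_rate_hz must be >= 0")


@dataclass(frozen=True)
class TrueEvent:
    """One injected saccade: onset, velocity-peak time, amplitude, kind."""

    onset_ms: float
    peak_time_ms: float
    amplitude_deg: float
    kind: str  # "tracking" | "extra"


@dataclass(frozen=True)
class GroundTruth:
    events: Tuple[TrueEvent, ...]
    deviation_deg: float
    latency_ms: float
    out_of_linear_range: bool

    @property
    def n_events(self) -> int:
        return len(self.events)


def stimulus_angle(
    protocol: StimulusProtocol, t_ms: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Stimulus angle θ(t) in degrees at time ``t_ms``.

    θ is ``theta_deg`` during the static window, then sweeps linearly to
    alternating ±excursion peaks at each direction-change time and returns
    to ``theta_deg`` at the end of the test. Raises on t outside [0, T].
    """
    t = np.asarray(t_ms, dtype=float)
    end_ms = protocol.test_duration_s * 1000.0
    if np.any(t < 0) or np.any(t > end_ms):
        raise ConfigError(f"time outside [0, {end_ms}] ms")
    knot_t = [0.0, protocol.static_duration_s * 1000.0]
    knot_a = [protocol.theta_deg, protocol.theta_deg]
    sign = 1.0
    for c in protocol.direction_change_times_s:
        knot_t.append(c * 1000.0)
        knot_a.append(protocol.theta_deg + sign * protocol.excursion_deg)
        sign = -sign
    knot_t.append(end_ms)
    knot_a.append(protocol.theta_deg)
    out = np.interp(t, knot_t, knot_a)
    return float(out) if np.isscalar(t_ms) else out


def _raised_cosine(n_dur: int) -> np.ndarray:
    """Unit step realised as a smooth raised-cosine transition."""
    x = np.linspace(0.0, math.pi, n_dur)
    return 0.5 * (1.0 - np.cos(x))


def _add_step(trace: np.ndarray, i0: int, amp: float, dur_samples: int) -> None:
    """Add a sigmoidal step of ``amp`` starting at index ``i0`` in place."""
    n = trace.size
    i1 = min(i0 + dur_samples, n)
    if i0 >= n:
        return
    ramp = _raised_cosine(dur_samples)[: i1 - i0]
    trace[i0:i1] += amp * ramp
    trace[i1:] += amp


def _add_flick(trace: np.ndarray, i0: int, amp: float, ts: float) -> Tuple[float, float]:
    """Add an involuntary flick: fast step out, 80 ms hold, slow glide back.

    Returns (peak_time_offset_ms, duration_ms of the fast phase).
    """
    dur = max(2, int(round(_saccade_duration_ms(amp) / ts)))
    hold = int(round(80.0 / ts))
    back = int(round(400.0 / ts))
    n = trace.size
    i1 = min(i0 + dur, n)
    ramp = _raised_cosine(dur)
    trace[i0:i1] += amp * ramp[: i1 - i0]
    i2 = min(i1 + hold, n)
    trace[i1:i2] += amp
    i3 = min(i2 + back, n)
    if i3 > i2:
        glide = amp * (1.0 - np.linspace(0.0, 1.0, i3 - i2, endpoint=False))
        trace[i2:i3] += glide
    return (dur * ts / 2.0, dur * ts)


def _micromovements(
    rng: np.random.Generator, n: int, fs_hz: float, sigma_deg: float
) -> np.ndarray:
    """Band-limited (≤2 Hz) zero-mean fixational activity, SD ``sigma_deg``.

    The low bandwidth keeps its velocity an order of magnitude below the
    saccade threshold, matching the slow character of real fixational drift.
    """
    if sigma_deg == 0.0 or n < 30:
        return np.zeros(n)
    # generate with 2 s margins and trim them, so filter edge transients
    # (the 2 Hz impulse response is ~0.5 s long) never reach the trace
    margin = int(round(2.0 * fs_hz))
    white = rng.standard_normal(n + 2 * margin)
    sos = sps.butter(2, 2.0, btype="low", fs=fs_hz, output="sos")
    slow = sps.sosfiltfilt(sos, white)[margin : margin + n]
    sd = slow.std()
    if sd == 0.0:
        return np.zeros(n)
    return slow * (sigma_deg / sd)


def _blink_pulse(n_dur: int) -> np.ndarray:
    """Asymmetric blink artefact: fast rise, slower decay (unit peak)."""
    up = _raised_cosine(max(2, n_dur // 4))
    down = 1.0 - _raised_cosine(n_dur - up.size)
    return np.concatenate([up, down])


def _place_extra_saccades(
    rng: np.random.Generator,
    n_extra: int,
    protocol: StimulusProtocol,
    saccade_times_ms: Sequence[float],
    min_gap_ms: float = 800.0,
) -> List[float]:
    """Draw injection times for involuntary saccades.

    Times are kept inside the tracking phase, clear of the static window
    (which defines the deviation feature), of each commanded catch-up
    saccade and of each motion onset (which define the delay feature), and
    mutually separated, so the annotation stays unambiguous.
    """
    end_ms = protocol.test_duration_s * 1000.0
    lo = protocol.motion_onsets_ms[0] + 1500.0
    hi = end_ms - 1500.0
    forbidden = [(s - min_gap_ms, s + min_gap_ms) for s in saccade_times_ms]
    forbidden += [(o - min_gap_ms, o + min_gap_ms) for o in protocol.motion_onsets_ms]
    placed: List[float] = []
    attempts = 0
    while len(placed) < n_extra:
        attempts += 1
        if attempts > 5000:
            raise ConfigError(
                f"cannot place {n_extra} extra saccades in the tracking phase"
            )
        t = float(rng.uniform(lo, hi))
        if any(a <= t <= b for a, b in forbidden):
            continue
        if any(abs(t - p) < min_gap_ms for p in placed):
            continue
        placed.append(t)
    return sorted(placed)


def generate_recording(
    profile: SubjectProfile,
    protocol: StimulusProtocol = StimulusProtocol(),
    cal: CalibrationConstants = CalibrationConstants(),
    sampling_interval_ms: float = 1.0,
) -> Tuple[EOGRecording, GroundTruth]:
    """Synthesise one labelled EOG recording.

    Returns the recording (µV) and its ground-truth annotation. The same
    profile (including ``seed``) reproduces the identical trace.
    """
    ts = float(sampling_interval_ms)
    if ts <= 0:
        raise ConfigError("sampling_interval_ms must be > 0")
    rng = np.random.default_rng(profile.seed)
    end_ms = protocol.test_duration_s * 1000.0
    n = int(round(end_ms / ts)) + 1
    t_ms = np.arange(n) * ts
    fs_hz = 1000.0 / ts

    theta = stimulus_angle(protocol, t_ms)

    # pursuit: velocity-matched tracking of the latency-delayed stimulus
    lat_samp = int(round(profile.latency_ms / ts))
    theta_delayed = np.concatenate(
        [np.full(min(lat_samp, n), theta[0]), theta[: max(n - lat_samp, 0)]]
    )[:n]
    vel = np.diff(theta_delayed, prepend=theta_delayed[0])
    first_saccade_ms = protocol.motion_onsets_ms[0] + profile.latency_ms
    i_first = int(round(first_saccade_ms / ts))
    pursuit = np.zeros(n)
    if i_first < n:
        pursuit[i_first:] = np.cumsum(vel[i_first:]) * profile.pursuit_gain

    eye = profile.deviation_deg + pursuit

    # catch-up saccades at each motion onset, closing the accumulated error
    events: List[TrueEvent] = []
    for onset in protocol.motion_onsets_ms:
        s_ms = onset + profile.latency_ms
        i0 = int(round(s_ms / ts))
        if i0 >= n:
            continue
        target = profile.pursuit_gain * (theta[i0] - protocol.theta_deg) \
            + protocol.theta_deg + profile.deviation_deg
        err = target - eye[i0]
        if abs(err) < MIN_SACCADE_DEG:
            continue
        dur = max(2, int(round(_saccade_duration_ms(err) / ts)))
        _add_step(eye, i0, err, dur)
        events.append(
            TrueEvent(
                onset_ms=s_ms,
                peak_time_ms=s_ms + dur * ts / 2.0,
                amplitude_deg=err,
                kind="tracking",
            )
        )

    # involuntary extra saccades (flicks) in the tracking phase
    extra_times = _place_extra_saccades(
        rng, profile.n_extra_saccades, protocol, [e.onset_ms for e in events]
    )
    for t0 in extra_times:
        amp = float(rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0]))
        i0 = int(round(t0 / ts))
        peak_off, _dur = _add_flick(eye, i0, amp, ts)
        events.append(
            TrueEvent(
                onset_ms=t0,
                peak_time_ms=t0 + peak_off,
                amplitude_deg=amp,
                kind="extra",
            )
        )
    events.sort(key=lambda e: e.onset_ms)

    angle = eye + _micromovements(
        rng, n, fs_hz, profile.micromovement_amplitude_deg / 3.0
    )
    out_of_range = bool(np.any(np.abs(angle) > cal.linear_range_deg))

    volts = cal.sensitivity_uV_per_deg * angle
    volts = volts + profile.drift_uV_per_s * (t_ms / 1000.0)
    if profile.noise_uV_rms > 0:
        volts = volts + rng.normal(0.0, profile.noise_uV_rms, n)
    if profile.blink_rate_hz > 0:
        n_blinks = rng.poisson(profile.blink_rate_hz * end_ms / 1000.0)
        dur = int(round(250.0 / ts))
        pulse = _blink_pulse(dur)
        for _ in range(n_blinks):
            i0 = int(rng.integers(0, max(n - dur, 1)))
            volts[i0 : i0 + dur] += 120.0 * pulse[: n - i0]

    rec = EOGRecording(samples=volts, sampling_interval_ms=ts)
    truth = GroundTruth(
        events=tuple(events),
        deviation_deg=profile.deviation_deg,
        latency_ms=profile.latency_ms,
        out_of_linear_range=out_of_range,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortMember:
    recording: EOGRecording
    truth: GroundTruth
    label: str  # "ataxia" | "healthy"
    profile: SubjectProfile


def healthy_profile(rng: np.random.Generator, **overrides) -> SubjectProfile:
    """Draw a profile satisfying every screening threshold with margin.

    Healthy subjects make the commanded catch-up saccades plus at most one
    involuntary one (N ≤ 6), fixate within ~1° of the target, and react
    within the normal 120–220 ms band.
    """
    params = dict(
        n_extra_saccades=int(rng.integers(0, 2)),
        deviation_deg=float(rng.uniform(-1.2, 1.2)),
        latency_ms=float(rng.uniform(120.0, 220.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return SubjectProfile(**params)


def ataxic_profile(rng: np.random.Generator, **overrides) -> SubjectProfile:
    """Draw a profile violating at least one screening threshold with margin.

    One to three of the axes (fixation instability → extra saccades, gaze
    deviation, reaction delay) are drawn abnormal; the rest stay in the
    healthy band.
    """
    axes = ["ros", "deviation", "delay"]
    k = int(rng.integers(1, 4))
    abnormal = set(rng.choice(axes, size=k, replace=False).tolist())
    params = dict(
        n_extra_saccades=int(rng.integers(3, 9))
        if "ros" in abnormal
        else int(rng.integers(0, 2)),
        deviation_deg=float(rng.uniform(4.5, 8.0) * rng.choice([-1.0, 1.0]))
        if "deviation" in abnormal
        else float(rng.uniform(-1.2, 1.2)),
        latency_ms=float(rng.uniform(350.0, 600.0))
        if "delay" in abnormal
        else float(rng.uniform(120.0, 220.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return SubjectProfile(**params)


def generate_cohort(
    n_ataxic: int = 5,
    n_healthy: int = 5,
    seed: Optional[int] = None,
    protocol: StimulusProtocol = StimulusProtocol(),
    cal: CalibrationConstants = CalibrationConstants(),
    sampling_interval_ms: float = 1.0,
    **profile_overrides,
) -> List[CohortMember]:
    """Generate a reproducible labelled cohort (ataxic first, then healthy).

    Mirrors the validation study design of five affected and five healthy
    subjects. ``profile_overrides`` apply to every drawn profile (e.g.
    ``noise_uV_rms=0`` for a noise-free cohort).
    """
    if n_ataxic < 0 or n_healthy < 0:
        raise ConfigError("cohort sizes must be >= 0")
    rng = np.random.default_rng(seed)
    members: List[CohortMember] = []
    for _ in range(n_ataxic):
        prof = ataxic_profile(rng, **profile_overrides)
        rec, truth = generate_recording(prof, protocol, cal, sampling_interval_ms)
        members.append(CohortMember(rec, truth, "ataxia", prof))
    for _ in range(n_healthy):
        prof = healthy_profile(rng, **profile_overrides)
        rec, truth = generate_recording(prof, protocol, cal, sampling_interval_ms)
        members.append(CohortMember(rec, truth, "healthy", prof))
    return members
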