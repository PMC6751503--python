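"""The three diagnostic features: rate of saccades, gaze deviation, delay.

* ROS = N / T — saccade count over the test duration (T = 45 s by default).
* Deviation ϕ = φ − θ, with gaze angle φ = V / S estimated from the mean
  filtered amplitude V over the static-fixation window and the dipole
  sensitivity S (16 µV/° horizontally). ϕ is signed: positive means the
  gaze leads (advance), negative that it lags (delay) the stimulus.
* Response delay D = n · Ts — time from the first stimulus-motion onset to
  the onset of the first saccade after it. A recording with no such saccade
  yields the :data:`~eogscreen.model.NO_RESPONSE` sentinel (``inf``), which
  always classifies as an abnormal delay.

:func:`extract_features` chains preprocessing → detection → the three
computations into a single :class:`~eogscreen.model.FeatureSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence

import numpy as np

from .model import (
    CalibrationConstants,
    ConfigError,
    EOGRecording,
    FeatureSet,
    NO_RESPONSE,
    PipelineError,
    StimulusProtocol,
)
from .preprocessing import (
    DerivativeParams,
    FilterSpec,
    central_difference,
    lowpass_filter,
    smooth_series,
)
from .detection import SaccadeDetectorConfig, SaccadeEvent, detect_saccades
from .utils import round_half_up

__all__ = [
    "GazeEstimate",
    "DeviationResult",
    "DelayResult",
    "compute_ros",
    "estimate_gaze_angle",
    "compute_deviation",
    "compute_delay",
    "extract_features",
]


def compute_ros(
    n_saccades: int, test_duration_s: float, ndigits: Optional[int] = 2
) -> float:
    """Rate of saccades N / T, rounded (half-up) to ``ndigits`` decimals.

    Pass ``ndigits=None`` for the unrounded quotient. E.g. 6 saccades over
    the default 45 s test give 0.13, the healthy upper bound.
    """
    if n_saccades < 0:
        raise ConfigError("n_saccades must be >= 0")
    if not (test_duration_s > 0):
        raise ConfigError(f"test duration must be > 0, got {test_duration_s}")
    ros = n_saccades / test_duration_s
    return ros if ndigits is None else round_half_up(ros, ndigits)


@dataclass(frozen=True)
class GazeEstimate:
    """Signed gaze angle φ = V / S with a linearity flag."""

    degrees: float
    in_linear_range: bool


def estimate_gaze_angle(
    static_amplitude_uV: float, cal: CalibrationConstants = CalibrationConstants()
) -> GazeEstimate:
    """Invert the dipole calibration: φ = V / S.

    Angles beyond the calibration's linear range are returned flagged
    (``in_linear_range=False``) rather than raising — the value is still the
    best linear estimate, it is just untrustworthy.
    """
    phi = static_amplitude_uV / cal.sensitivity_uV_per_deg
    return GazeEstimate(degrees=phi, in_linear_range=cal.in_linear_range(phi))


@dataclass(frozen=True)
class DeviationResult:
    deviation_deg: float
    gaze_angle_deg: float
    static_amplitude_uV: float
    in_linear_range: bool


def compute_deviation(
    rec: EOGRecording,
    protocol: StimulusProtocol = StimulusProtocol(),
    cal: CalibrationConstants = CalibrationConstants(),
    settle_ms: float = 500.0,
    filter_spec: Optional[FilterSpec] = FilterSpec(),
) -> DeviationResult:
    """Gaze deviation ϕ = φ − θ over the static-fixation window.

    V is the mean filtered amplitude over ``[settle_ms, static_duration]``;
    the settle time discards the initial orienting movement. Pass
    ``filter_spec=None`` if ``rec`` is already filtered.
    """
    static_ms = protocol.static_duration_s * 1000.0
    if settle_ms >= static_ms:
        raise ConfigError(
            f"settle_ms ({settle_ms}) must be shorter than the static window "
            f"({static_ms} ms)"
        )
    if rec.start_time_ms > settle_ms or rec.time_ms[-1] < static_ms:
        raise ConfigError("recording does not cover the static window")
    filtered = lowpass_filter(rec, filter_spec) if filter_spec is not None else rec
    i0 = filtered.index_at(settle_ms)
    i1 = filtered.index_at(static_ms)
    v = float(np.mean(filtered.samples[i0 : i1 + 1]))
    gaze = estimate_gaze_angle(v, cal)
    return DeviationResult(
        deviation_deg=gaze.degrees - protocol.theta_deg,
        gaze_angle_deg=gaze.degrees,
        static_amplitude_uV=v,
        in_linear_range=gaze.in_linear_range,
    )


@dataclass(frozen=True)
class DelayResult:
    """Response delay D = n · Ts; ``n_samples`` is None for no response."""

    delay_ms: float
    n_samples: Optional[int]

    @property
    def responded(self) -> bool:
        return math.isfinite(self.delay_ms)


def compute_delay(
    events: Sequence[SaccadeEvent],
    protocol: StimulusProtocol = StimulusProtocol(),
    sampling_interval_ms: float = 1.0,
    mode: Literal["first", "mean"] = "first",
) -> DelayResult:
    """Saccadic reaction time to stimulus motion.

    ``first`` (default): time from the first motion onset (end of the static
    window) to the onset of the first saccade event at or after it.
    ``mean``: the average of per-onset delays over every motion onset that
    has a responding saccade before the next onset.

    With no responding saccade at all the result is the
    :data:`~eogscreen.model.NO_RESPONSE` sentinel.
    """
    onsets = protocol.motion_onsets_ms
    end_ms = protocol.test_duration_s * 1000.0
    if mode not in ("first", "mean"):
        raise ConfigError(f"unknown delay mode {mode!r}")
    onset_list = [onsets[0]] if mode == "first" else list(onsets)
    delays: List[float] = []
    for i, onset in enumerate(onset_list):
        horizon = onset_list[i + 1] if i + 1 < len(onset_list) else end_ms
        if mode == "first":
            horizon = end_ms
        responding = [
            ev.onset_ms for ev in events if onset <= ev.onset_ms < horizon
        ]
        if responding:
            delays.append(min(responding) - onset)
    if not delays:
        return DelayResult(delay_ms=NO_RESPONSE, n_samples=None)
    d = float(np.mean(delays))
    return DelayResult(delay_ms=d, n_samples=int(round(d / sampling_interval_ms)))


def extract_features(
    rec: EOGRecording,
    protocol: StimulusProtocol = StimulusProtocol(),
    cal: CalibrationConstants = CalibrationConstants(),
    detector_cfg: SaccadeDetectorConfig = SaccadeDetectorConfig(),
    *,
    filter_spec: FilterSpec = FilterSpec(),
    derivative_params: DerivativeParams = DerivativeParams(),
    smooth: Literal["mean", "median", "off"] = "off",
    smooth_window: int = 100,
    settle_ms: float = 500.0,
    delay_mode: Literal["first", "mean"] = "first",
) -> FeatureSet:
    """Run the full feature pipeline on one recording.

    Stages: low-pass filter → central difference → optional trailing
    smoothing of the derivative → threshold detection → ROS / deviation /
    delay. Stage failures re-raise as :class:`PipelineError` naming the
    stage. Note the trailing smoother attenuates saccadic derivative peaks
    by roughly its window length, so leaving it ``off`` (the default) is
    required for the stock 0.48 µV/ms threshold to see 1–3° saccades.
    """
    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    filtered = _stage("filter", lambda: lowpass_filter(rec, filter_spec))
    deriv = _stage(
        "derivative", lambda: central_difference(filtered, derivative_params)
    )
    deriv = _stage(
        "smoothing", lambda: smooth_series(deriv, smooth_window, smooth)
    )
    events = _stage(
        "detection",
        lambda: detect_saccades(
            deriv,
            detector_cfg,
            sampling_interval_ms=rec.sampling_interval_ms,
            start_time_ms=rec.start_time_ms,
        ),
    )
    n = len(events)
    ros = _stage("ros", lambda: compute_ros(n, protocol.test_duration_s))
    dev = _stage(
        "deviation",
        lambda: compute_deviation(
            filtered, protocol, cal, settle_ms=settle_ms, filter_spec=None
        ),
    )
    delay = _stage(
        "delay",
        lambda: compute_delay(
            events, protocol, rec.sampling_interval_ms, mode=delay_mode
        ),
    )
    return FeatureSet(
        ros=ros,
        n_saccades=n,
        deviation_deg=dev.deviation_deg,
        gaze_angle_deg=dev.gaze_angle_deg,
        static_amplitude_uV=dev.static_amplitude_uV,
        delay_ms=delay.delay_ms,
        n_delay_samples=delay.n_samples,
        gaze_in_linear_range=dev.in_linear_range,
    )
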