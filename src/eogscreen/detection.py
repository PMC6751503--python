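"""Velocity-threshold saccade detection and threshold calibration.

A saccade is a rapid re-fixation of gaze; on the EOG it appears as a steep
amplitude step, hence a derivative peak. Detection marks every sample whose
velocity magnitude reaches a threshold ``Th`` (µV/ms), groups consecutive
supra-threshold samples into runs, merges runs separated by less than a
refractory gap (one saccade, one event), and discards runs shorter than a
minimum duration. The event count ``N`` feeds the rate-of-saccades feature.

``Th`` can be set explicitly or calibrated from fixation-only recordings of
healthy subjects: the noise floor of the rectified velocity (mean + k·SD)
guarded from below by a conventional angular-velocity criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .model import (
    CalibrationConstants,
    ConfigError,
    EmptyInputError,
    EOGRecording,
)
from .preprocessing import DerivativeParams, FilterSpec, central_difference, lowpass_filter

__all__ = [
    "SaccadeDetectorConfig",
    "SaccadeEvent",
    "detect_saccades",
    "calibrate_threshold",
    "threshold_from_noise",
    "DEFAULT_VELOCITY_FLOOR_DEG_PER_S",
]

#: Conventional saccade angular-velocity criterion used as the calibration
#: floor: 30°/s, i.e. 30 × 16 µV/° = 480 µV/s = 0.48 µV/ms horizontally.
DEFAULT_VELOCITY_FLOOR_DEG_PER_S: float = 30.0


@dataclass(frozen=True)
class SaccadeDetectorConfig:
    """Detector settings.

    ``threshold_uV_per_ms`` has no published value for this device; the
    default is the 30°/s criterion expressed through the 16 µV/° horizontal
    sensitivity (0.48 µV/ms) and is fully overridable, e.g. via
    :func:`calibrate_threshold`.
    """

    threshold_uV_per_ms: Optional[float] = 0.48
    refractory_ms: float = 50.0
    min_duration_ms: float = 3.0
    use_absolute: bool = True

    def __post_init__(self) -> None:
        if self.threshold_uV_per_ms is not None and not (self.threshold_uV_per_ms > 0):
            raise ConfigError("threshold must be > 0")
        if self.refractory_ms < 0:
            raise ConfigError("refractory_ms must be >= 0")
        if not (self.min_duration_ms > 0):
            raise ConfigError("min_duration_ms must be positive")


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade.

    ``direction`` is the sign of the derivative at the peak: +1 for motion
    toward the positive electrode, −1 away from it.
    """

    onset_ms: float
    offset_ms: float
    peak_derivative_uV_per_ms: float
    peak_time_ms: float
    direction: int

    def __post_init__(self) -> None:
        if not (self.onset_ms <= self.peak_time_ms <= self.offset_ms):
            raise ConfigError(
                f"event times out of order: onset {self.onset_ms}, "
                f"peak {self.peak_time_ms}, offset {self.offset_ms}"
            )
        if self.direction not in (-1, 1):
            raise ConfigError("direction must be +1 or -1")


def detect_saccades(
    deriv: np.ndarray,
    cfg: SaccadeDetectorConfig = SaccadeDetectorConfig(),
    sampling_interval_ms: float = 1.0,
    start_time_ms: float = 0.0,
) -> List[SaccadeEvent]:
    """Extract saccade events from a derivative series (µV/ms).

    Returns events ordered by onset. Raises :class:`EmptyInputError` on an
    empty series and :class:`ConfigError` if no threshold is set.
    """
    deriv = np.asarray(deriv, dtype=float)
    if deriv.size == 0:
        raise EmptyInputError("empty derivative series")
    th = cfg.threshold_uV_per_ms
    if th is None:
        raise ConfigError(
            "detector threshold unset; set threshold_uV_per_ms explicitly "
            "or run calibrate_threshold"
        )
    ts = sampling_interval_ms
    score = np.abs(deriv) if cfg.use_absolute else deriv
    mask = score >= th
    if not mask.any():
        return []

    # maximal supra-threshold runs as [start, end] sample indices (inclusive)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2] - 1

    # merge runs whose inter-run gap is shorter than the refractory period
    merged = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        gap_ms = (s - merged[-1][1] - 1) * ts
        if gap_ms < cfg.refractory_ms:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    min_samples = max(1, int(math.ceil(cfg.min_duration_ms / ts)))
    events: List[SaccadeEvent] = []
    for s, e in merged:
        if (e - s + 1) < min_samples:
            continue
        seg = deriv[s : e + 1]
        pk = int(np.argmax(np.abs(seg)))
        peak_val = float(seg[pk])
        events.append(
            SaccadeEvent(
                onset_ms=start_time_ms + s * ts,
                offset_ms=start_time_ms + e * ts,
                peak_derivative_uV_per_ms=peak_val,
                peak_time_ms=start_time_ms + (s + pk) * ts,
                direction=1 if peak_val >= 0 else -1,
            )
        )
    return events


def threshold_from_noise(abs_deriv: np.ndarray, k: float) -> float:
    """Noise-floor threshold: mean + k·SD of a rectified velocity sample."""
    abs_deriv = np.asarray(abs_deriv, dtype=float)
    if abs_deriv.size == 0:
        raise EmptyInputError("no derivative samples for calibration")
    return float(abs_deriv.mean() + k * abs_deriv.std(ddof=0))


def calibrate_threshold(
    fixation_recs: Sequence[EOGRecording],
    k: float = 5.0,
    cal: CalibrationConstants = CalibrationConstants(),
    *,
    filter_spec: Optional[FilterSpec] = FilterSpec(),
    derivative_params: DerivativeParams = DerivativeParams(),
    velocity_floor_deg_per_s: float = DEFAULT_VELOCITY_FLOOR_DEG_PER_S,
    base: SaccadeDetectorConfig = SaccadeDetectorConfig(),
) -> SaccadeDetectorConfig:
    """Empirically set ``Th`` from fixation-only recordings of healthy eyes.

    Each recording is filtered (unless ``filter_spec`` is None),
    differentiated, and rectified; ``Th`` is the larger of the pooled noise
    floor ``mean + k·SD`` and the angular-velocity floor
    ``velocity_floor_deg_per_s × S / 1000`` µV/ms. Degenerate (constant)
    inputs trigger a warning and fall back to the velocity floor.
    """
    if len(fixation_recs) == 0:
        raise EmptyInputError("no fixation recordings supplied")
    floor = velocity_floor_deg_per_s * cal.sensitivity_uV_per_deg / 1000.0
    pooled = []
    for rec in fixation_recs:
        r = lowpass_filter(rec, filter_spec) if filter_spec is not None else rec
        pooled.append(np.abs(central_difference(r, derivative_params)))
    abs_deriv = np.concatenate(pooled)
    if abs_deriv.std(ddof=0) == 0.0:
        warnings.warn(
            "fixation recordings are constant; falling back to the "
            "velocity-floor threshold",
            stacklevel=2,
        )
        th = floor
    else:
        th = max(threshold_from_noise(abs_deriv, k), floor)
    if not (th > 0):
        raise ConfigError("calibration produced a non-positive threshold")
    return replace(base, threshold_uV_per_ms=th)
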