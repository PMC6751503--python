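"""Core domain types and delimited-ASCII I/O for EOG recordings.

Conventions used throughout the package:

* amplitudes are in microvolts (µV);
* time is in milliseconds at every interface; sample ``k`` of a recording
  occupies time ``start_time_ms + k * sampling_interval_ms``;
* gaze angles are in degrees, positive toward the positive electrode.

The electrooculogram is the surface recording of the corneo-retinal dipole:
the cornea is electrically positive relative to the retina, so a horizontal
eye rotation produces a potential roughly proportional to gaze angle
(about 16 µV per degree horizontally, nearly linear within ±50°).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "EOGError",
    "RecordingParseError",
    "IntegrityError",
    "EmptyInputError",
    "ConfigError",
    "LengthError",
    "PipelineError",
    "Channel",
    "EOGRecording",
    "CalibrationConstants",
    "StimulusProtocol",
    "FeatureSet",
    "NO_RESPONSE",
    "read_recording",
    "write_recording",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EOGError(Exception):
    """Base class for all errors raised by this package."""


class RecordingParseError(EOGError):
    """A recording file contains a malformed row or header."""


class IntegrityError(EOGError):
    """A recording's time base is non-monotone or non-uniform."""


class EmptyInputError(EOGError):
    """An operation received an empty signal or file."""


class ConfigError(EOGError):
    """A parameter value is invalid or inconsistent."""


class LengthError(EOGError):
    """An input is too short for the requested operation."""


class PipelineError(EOGError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


#: Sentinel delay value for a recording with no saccade after stimulus onset.
#: Compares as larger than any finite delay threshold, so a missing response
#: always classifies as an abnormal delay.
NO_RESPONSE: float = math.inf


class Channel(str, enum.Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class EOGRecording:
    """A single-channel EOG trace sampled on a uniform time grid.

    Parameters
    ----------
    samples
        Amplitudes in µV. Must be finite and non-empty.
    sampling_interval_ms
        Ts, the sample spacing in milliseconds (default 1.0, i.e. 1 kHz).
    channel
        Electrode derivation; the analysis pipeline operates on the
        horizontal channel.
    start_time_ms
        Time of the first sample.
    """

    samples: np.ndarray
    sampling_interval_ms: float = 1.0
    channel: Channel = Channel.HORIZONTAL
    start_time_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise EmptyInputError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise IntegrityError("recording contains non-finite amplitudes")
        if not (self.sampling_interval_ms > 0):
            raise ConfigError(
                f"sampling_interval_ms must be > 0, got {self.sampling_interval_ms}"
            )
        self.channel = Channel(self.channel)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.sampling_interval_ms

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) * self.sampling_interval_ms

    @property
    def time_ms(self) -> np.ndarray:
        """Time stamps of every sample, in milliseconds."""
        return self.start_time_ms + np.arange(self.n_samples) * self.sampling_interval_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to time ``t_ms`` (clipped to range)."""
        i = int(round((t_ms - self.start_time_ms) / self.sampling_interval_ms))
        return min(max(i, 0), self.n_samples - 1)

    def with_samples(self, samples: np.ndarray) -> "EOGRecording":
        """Copy of this recording carrying new sample values."""
        return EOGRecording(
            samples=samples,
            sampling_interval_ms=self.sampling_interval_ms,
            channel=self.channel,
            start_time_ms=self.start_time_ms,
        )


# ---------------------------------------------------------------------------
# Calibration and stimulus protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstants:
    """Angle-to-voltage calibration of the EOG dipole.

    The horizontal derivation yields about 16 µV per degree of rotation and
    is approximately linear within ±50°; the vertical derivation yields
    about 14 µV/° within ±30°. Angle estimates outside the linear range are
    flagged, never silently returned.
    """

    sensitivity_uV_per_deg: float = 16.0
    linear_range_deg: float = 50.0

    def __post_init__(self) -> None:
        if not (self.sensitivity_uV_per_deg > 0):
            raise ConfigError("sensitivity must be > 0")
        if not (self.linear_range_deg > 0):
            raise ConfigError("linear range must be > 0")

    @classmethod
    def horizontal(cls) -> "CalibrationConstants":
        return cls(16.0, 50.0)

    @classmethod
    def vertical(cls) -> "CalibrationConstants":
        return cls(14.0, 30.0)

    def in_linear_range(self, angle_deg: float) -> bool:
        return abs(angle_deg) <= self.linear_range_deg


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and geometry of the visual tracking test.

    The stimulus is static at ``theta_deg`` for ``static_duration_s`` (gaze
    deviation is measured there), then sweeps horizontally at constant
    angular speed, reversing direction at each entry of
    ``direction_change_times_s`` (peaks of ±``excursion_deg``) and returning
    to centre at ``test_duration_s``.
    """

    static_duration_s: float = 5.0
    test_duration_s: float = 45.0
    direction_change_times_s: tuple = (10.0, 20.0, 30.0, 40.0)
    theta_deg: float = 0.0
    excursion_deg: float = 32.4

    def __post_init__(self) -> None:
        if not (0 < self.static_duration_s < self.test_duration_s):
            raise ConfigError(
                "require 0 < static_duration_s < test_duration_s, got "
                f"{self.static_duration_s} / {self.test_duration_s}"
            )
        times = tuple(float(t) for t in self.direction_change_times_s)
        object.__setattr__(self, "direction_change_times_s", times)
        if len(times) == 0:
            raise ConfigError("at least one direction change is required")
        if any(
            not (self.static_duration_s < t < self.test_duration_s) for t in times
        ):
            raise ConfigError(
                "direction changes must lie strictly inside "
                "(static_duration_s, test_duration_s)"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("direction change times must be strictly increasing")
        if not (self.excursion_deg > 0):
            raise ConfigError("excursion_deg must be > 0")

    @property
    def motion_onsets_ms(self) -> tuple:
        """Times at which the stimulus starts or reverses its motion.

        The first entry is the end of the static window (motion start); the
        remainder are the direction changes. The response-delay feature is
        measured from the first entry by default.
        """
        return (self.static_duration_s * 1000.0,) + tuple(
            t * 1000.0 for t in self.direction_change_times_s
        )


# ---------------------------------------------------------------------------
# Feature container
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """The three diagnostic parameters plus their intermediates.

    ``ros``
        Rate of saccades, N / T in saccades per second (2-decimal report).
    ``deviation_deg``
        ϕ = φ − θ: signed angular error of gaze versus the static stimulus.
    ``delay_ms``
        D = n · Ts: saccadic reaction time to stimulus motion;
        :data:`NO_RESPONSE` (``inf``) when no saccade follows the onset.
    """

    ros: float
    n_saccades: int
    deviation_deg: float
    gaze_angle_deg: float
    static_amplitude_uV: float
    delay_ms: float
    n_delay_samples: Optional[int]
    gaze_in_linear_range: bool = True

    def __post_init__(self) -> None:
        if self.ros is not None and self.ros < 0:
            raise ConfigError("ros must be >= 0")
        if self.n_saccades is not None and self.n_saccades < 0:
            raise ConfigError("n_saccades must be >= 0")
        if self.delay_ms is not None and self.delay_ms < 0:
            raise ConfigError("delay_ms must be >= 0")


# ---------------------------------------------------------------------------
# ASCII I/O
# ---------------------------------------------------------------------------

_SPLIT_RE = re.compile(r"[,\t;]\s*|\s+")

_HEADER_KEYS = {"sampling_interval_ms", "channel", "start_time_ms", "units", "columns"}


def read_recording(
    path: Union[str, Path],
    *,
    sampling_interval_ms: Optional[float] = None,
    channel: Optional[Union[str, Channel]] = None,
) -> EOGRecording:
    """Read a delimited-ASCII EOG recording.

    Rows are either ``time_ms, amplitude_uV`` pairs or bare amplitudes;
    ``#``-prefixed header lines may carry ``sampling_interval_ms``,
    ``channel`` and ``start_time_ms``. Keyword arguments override missing
    header fields (header wins over defaults; explicit timestamps win over
    both for the time base).

    Raises
    ------
    RecordingParseError
        on a malformed row (the message names the line).
    IntegrityError
        if timestamps are non-monotone, duplicated, or non-uniform.
    EmptyInputError
        if the file contains no data rows.
    """
    path = Path(path)
    header: dict = {}
    times: list = []
    values: list = []
    ncols: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip().lower()] = val.strip()
                continue
            parts = [p for p in _SPLIT_RE.split(s) if p]
            if len(parts) not in (1, 2):
                raise RecordingParseError(
                    f"{path.name}, line {lineno}: expected 1 or 2 columns, got {len(parts)}"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise RecordingParseError(
                    f"{path.name}, line {lineno}: inconsistent column count"
                )
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                raise RecordingParseError(
                    f"{path.name}, line {lineno}: non-numeric field in {s!r}"
                ) from None
            if ncols == 2:
                times.append(nums[0])
                values.append(nums[1])
            else:
                values.append(nums[0])

    if not values:
        raise EmptyInputError(f"{path.name}: no data rows")

    ts = sampling_interval_ms
    if "sampling_interval_ms" in header:
        ts = float(header["sampling_interval_ms"])
    start = float(header.get("start_time_ms", 0.0))

    if times:
        t = np.asarray(times)
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2
            raise IntegrityError(
                f"{path.name}: timestamps not strictly increasing at data row {bad}"
            )
        inferred = float(np.median(dt)) if dt.size else (ts or 1.0)
        ts = ts if ts is not None else inferred
        if dt.size and np.max(np.abs(dt - ts)) > 1e-3 * ts:
            raise IntegrityError(
                f"{path.name}: non-uniform time base (expected Ts={ts} ms)"
            )
        start = float(t[0])
    if ts is None:
        ts = 1.0

    chan = header.get("channel", None) or channel or Channel.HORIZONTAL
    return EOGRecording(
        samples=np.asarray(values, dtype=float),
        sampling_interval_ms=float(ts),
        channel=Channel(chan),
        start_time_ms=start,
    )


def write_recording(rec: EOGRecording, path: Union[str, Path]) -> Path:
    """Write a recording as self-describing delimited ASCII.

    The layout is a ``#`` header (rate, channel, units) followed by one
    ``time_ms,amplitude_uV`` row per sample; :func:`read_recording` inverts
    it exactly up to the written precision (6 decimals).
    """
    path = Path(path)
    lines = [
        "# eogscreen recording",
        f"# sampling_interval_ms: {rec.sampling_interval_ms!r}",
        f"# channel: {rec.channel.value}",
        f"# start_time_ms: {rec.start_time_ms!r}",
        "# units: uV",
        "# columns: time_ms,amplitude_uV",
    ]
    t = rec.time_ms
    lines.extend(f"{ti:.6f},{vi:.6f}" for ti, vi in zip(t, rec.samples))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise EOGError(f"cannot write recording to {path}: {exc}") from exc
    return path
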