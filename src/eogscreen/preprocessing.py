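"""Noise removal, velocity estimation, and trailing smoothing.

The pipeline's preprocessing stages are:

1. a 30 Hz low-pass 9th-order Butterworth filter (zero-phase by default);
2. a finite central-difference derivative, giving eye velocity in µV/ms;
3. an optional trailing ("last 100 samples") mean or median smoother used
   to visualise slow pursuit (≈0) versus rapid-eye-movement peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .model import ConfigError, EOGRecording, LengthError

__all__ = [
    "FilterSpec",
    "DerivativeParams",
    "lowpass_filter",
    "central_difference",
    "moving_average",
    "moving_median",
    "smooth_series",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    Parameters
    ----------
    cutoff_hz
        −3 dB corner frequency; must be below the recording's Nyquist.
    order
        Filter order (9 by default). Realised as a cascade of second-order
        sections for numerical robustness at high order.
    mode
        ``zero_phase`` applies the filter forward and backward
        (no group delay, magnitude response squared); ``causal`` applies it
        once, as a real-time system would.
    """

    cutoff_hz: float = 30.0
    order: int = 9
    mode: Literal["zero_phase", "causal"] = "zero_phase"

    def __post_init__(self) -> None:
        if not (self.cutoff_hz > 0):
            raise ConfigError(f"cutoff_hz must be > 0, got {self.cutoff_hz}")
        if self.order < 1:
            raise ConfigError(f"order must be >= 1, got {self.order}")
        if self.mode not in ("zero_phase", "causal"):
            raise ConfigError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class DerivativeParams:
    """Half-window ``h`` (in samples) of the central difference."""

    h_samples: int = 1

    def __post_init__(self) -> None:
        if self.h_samples < 1:
            raise ConfigError(f"h_samples must be >= 1, got {self.h_samples}")


def lowpass_filter(rec: EOGRecording, spec: FilterSpec = FilterSpec()) -> EOGRecording:
    """Low-pass filter a recording, preserving length, rate and metadata.

    Raises :class:`ConfigError` if the cutoff reaches the Nyquist frequency
    and :class:`LengthError` if the recording is too short for a stable
    transient (length must exceed ``3 * order``).
    """
    nyquist = rec.sampling_rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ConfigError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz at "
            f"{rec.sampling_rate_hz} Hz sampling"
        )
    if rec.n_samples <= 3 * spec.order:
        raise LengthError(
            f"recording of {rec.n_samples} samples too short for order "
            f"{spec.order} filtering (need > {3 * spec.order})"
        )
    sos = sps.butter(
        spec.order, spec.cutoff_hz, btype="low", fs=rec.sampling_rate_hz, output="sos"
    )
    if spec.mode == "zero_phase":
        default_padlen = 3 * (2 * sos.shape[0] + 1)
        padlen = min(default_padlen, rec.n_samples - 1)
        # symmetric padding: odd extension pins the output to the raw edge
        # sample, which injects a spurious velocity spike at the boundary
        out = sps.sosfiltfilt(sos, rec.samples, padtype="even", padlen=padlen)
    else:
        out = sps.sosfilt(sos, rec.samples)
    return rec.with_samples(out)


def central_difference(
    rec: EOGRecording, params: DerivativeParams = DerivativeParams()
) -> np.ndarray:
    """Finite central-difference derivative of a recording, in µV/ms.

    Interior points get ``(f(x0 + h) − f(x0 − h)) / (2 h Ts)``; the first and
    last ``h`` points fall back to one-sided differences over the same span,
    so the output has the same length as the input and the derivative of an
    affine signal is exact everywhere.
    """
    h = params.h_samples
    x = rec.samples
    n = x.size
    if n < 2 * h + 1:
        raise LengthError(
            f"need at least {2 * h + 1} samples for central difference with "
            f"h={h}, got {n}"
        )
    ts = rec.sampling_interval_ms
    d = np.empty(n, dtype=float)
    d[h:-h] = (x[2 * h:] - x[: -2 * h]) / (2.0 * h * ts)
    d[:h] = (x[h : 2 * h] - x[:h]) / (h * ts)
    d[-h:] = (x[-h:] - x[-2 * h : -h]) / (h * ts)
    return d


def moving_average(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Causal (trailing) mean over the last ``window`` samples.

    During warm-up (the first ``window − 1`` samples) the effective window
    is the number of samples seen so far, so the output starts at the first
    input value rather than at an artificial zero.
    """
    series = np.asarray(series, dtype=float)
    _check_window(series, window)
    c = np.cumsum(series)
    out = np.empty_like(series)
    out[:window] = c[:window] / np.arange(1, min(window, series.size) + 1)
    if series.size > window:
        out[window:] = (c[window:] - c[:-window]) / window
    return out


def moving_median(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Causal (trailing) median over the last ``window`` samples."""
    series = np.asarray(series, dtype=float)
    _check_window(series, window)
    return (
        pd.Series(series).rolling(window, min_periods=1).median().to_numpy()
    )


def smooth_series(
    series: np.ndarray,
    window: int = 100,
    method: Literal["mean", "median", "off"] = "mean",
) -> np.ndarray:
    """Dispatch to :func:`moving_average` / :func:`moving_median`, or pass through."""
    if method == "off":
        return np.asarray(series, dtype=float)
    if method == "mean":
        return moving_average(series, window)
    if method == "median":
        return moving_median(series, window)
    raise ConfigError(f"unknown smoothing method {method!r}")


def _check_window(series: np.ndarray, window: int) -> None:
    if window < 1:
        raise ConfigError(f"window must be >= 1, got {window}")
    if series.size == 0:
        raise LengthError("empty series")
    if window > series.size:
        raise LengthError(
            f"window {window} exceeds series length {series.size}"
        )
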