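import numpy as np
import pytest

from eogscreen import (
    CalibrationConstants,
    EOGRecording,
    StimulusProtocol,
)


@pytest.fixture
def cal():
    return CalibrationConstants()


@pytest.fixture
def protocol():
    return StimulusProtocol()


@pytest.fixture
def make_recording():
    """Factory: wrap a plain array (or a constant) as a 1 kHz recording."""

    def _make(samples, ts=1.0, **kw):
        return EOGRecording(np.asarray(samples, dtype=float), sampling_interval_ms=ts, **kw)

    return _make


def brute_force_detect(deriv, th, refractory_ms=50.0, min_duration_ms=3.0,
                       ts=1.0, absolute=True):
    """Independent loop-based reference detector: mark every supra-threshold
    sample, group consecutive samples, merge across short gaps, drop short
    runs. Returns (onset_idx, offset_idx, peak_idx, peak_value) tuples."""
    score = [abs(v) for v in deriv] if absolute else list(deriv)
    marked = [i for i, v in enumerate(score) if v >= th]
    groups = []
    for i in marked:
        if groups and (i == groups[-1][-1] + 1
                       or (i - groups[-1][-1] - 1) * ts < refractory_ms):
            groups[-1].append(i)
        else:
            groups.append([i])
    min_samples = max(1, int(np.ceil(min_duration_ms / ts)))
    out = []
    for g in groups:
        s, e = g[0], g[-1]
        if e - s + 1 < min_samples:
            continue
        span = deriv[s : e + 1]
        pk = int(np.argmax(np.abs(span)))
        out.append((s, e, s + pk, float(span[pk])))
    return out
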