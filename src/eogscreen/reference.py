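"""Published reference cohort used to validate the decision rule.

Ten adult volunteers (five previously diagnosed with an ataxic disorder,
five neurologically healthy controls) performed the 45 s horizontal
tracking test; the table below records each subject's three screening
parameters and the evaluation outcome, as published with the screening
method. Each subject repeated the test three times, and the pooled 30-test
confusion counts are kept here as well. These are summary data, not raw
traces — no raw EOG recordings were deposited, which is why the synthetic
generator (:mod:`eogscreen.synth`) exists.
"""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd

from .diagnosis import ConfusionCounts
from .features import compute_ros
from .model import FeatureSet
from .utils import round_half_up

__all__ = [
    "reference_cohort",
    "reference_feature_sets",
    "VALIDATION_CONFUSION",
    "TEST_DURATION_S",
]

#: Duration of the tracking test the cohort performed.
TEST_DURATION_S = 45.0

#: Pooled confusion counts over the 30 screening tests (3 per subject).
VALIDATION_CONFUSION = ConfusionCounts(tp=13, fp=2, tn=12, fn=3)

# subject, age, sex, group, origin, ROS, |deviation| (deg), delay (ms), outcome
_ROWS = [
    ("a", 46, "M", "ataxia", "hereditary-unknown", 0.08, 21.03, 156, "positive"),
    ("b", 54, "M", "ataxia", "non-hereditary-accident", 0.13, 5.87, 615, "positive"),
    ("c", 60, "F", "ataxia", "hereditary-friedreich", 0.20, 2.08, 149, "positive"),
    ("d", 64, "M", "ataxia", "hereditary-unknown", 0.08, 1.60, 1340, "positive"),
    ("e", 56, "M", "ataxia", "hereditary-unknown", 0.13, 3.32, 128, "positive"),
    ("f", 41, "F", "healthy", None, 0.08, 0.45, 135, "negative"),
    ("g", 57, "M", "healthy", None, 0.11, 0.71, 174, "negative"),
    ("h", 32, "M", "healthy", None, 0.11, 2.26, 153, "negative"),
    ("i", 58, "F", "healthy", None, 0.08, 1.82, 139, "negative"),
    ("j", 46, "F", "healthy", None, 0.08, 0.94, 181, "negative"),
]

_COLUMNS = [
    "subject",
    "age",
    "sex",
    "group",
    "origin",
    "ros",
    "deviation_deg",
    "delay_ms",
    "reported_label",
]


def reference_cohort() -> pd.DataFrame:
    """The ten-subject validation cohort as a DataFrame (one row per subject)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reference_feature_sets(
    sensitivity_uV_per_deg: float = 16.0,
) -> List[Tuple[str, FeatureSet, str]]:
    """Rebuild a :class:`FeatureSet` per subject from the published summary.

    The published table reports the rounded ROS quotient; the saccade count
    is reconstructed as ``round(ROS × T)`` (e.g. 0.20 × 45 = 9). Deviation
    magnitudes are reported with θ = 0, so gaze angle equals deviation and
    the static amplitude is ``deviation × S``.

    Returns ``(subject, features, reported_label)`` triples.
    """
    out = []
    for row in _ROWS:
        subject, _age, _sex, _group, _origin, ros, dev, delay, label = row
        n = int(round_half_up(ros * TEST_DURATION_S, 0))
        fs = FeatureSet(
            ros=compute_ros(n, TEST_DURATION_S),
            n_saccades=n,
            deviation_deg=dev,
            gaze_angle_deg=dev,
            static_amplitude_uV=dev * sensitivity_uV_per_deg,
            delay_ms=float(delay),
            n_delay_samples=int(delay),
        )
        out.append((subject, fs, label))
    return out
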