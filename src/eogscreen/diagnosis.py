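"""The three-threshold screening rule and its evaluation metrics.

A test is *positive* (possible ataxia) if any of the three parameters
exceeds its healthy bound — the parameters carry equal weight, so the rule
is a pure OR:

* saccade count N > 6 (equivalently ROS > 0.13 at T = 45 s: four expected
  stimulus-following saccades plus a margin of two involuntary ones);
* |gaze deviation| > 3° (fixational micromovements reach ~1.5° and the EOG
  technique itself is accurate to about ±1.5°);
* response delay ≥ 300 ms (the upper end of published visual reaction
  times), with a missing response counting as an abnormal delay.

Boundary semantics: N = 6 and ϕ = 3.0° are still healthy ("equal or less",
"threshold of 3° is set"); D = 300 ms is already abnormal ("less than
300 ms for a healthy person"). The count comparison is done on the integer
N rather than the rounded quotient, since 6/45 = 0.1333 prints as 0.13.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .model import ConfigError, EOGError, FeatureSet
from .utils import round_half_up

__all__ = [
    "DecisionThresholds",
    "ParameterFlags",
    "EvaluationResult",
    "ConfusionCounts",
    "Metrics",
    "classify",
    "compute_metrics",
    "tabulate_confusion",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "positive"
NEGATIVE = "negative"

# label vocabularies accepted by tabulate_confusion
_POSITIVE_LABELS = {POSITIVE, "ataxia", "ataxic"}
_NEGATIVE_LABELS = {NEGATIVE, "healthy", "control"}


@dataclass(frozen=True)
class DecisionThresholds:
    max_saccades: int = 6
    max_deviation_deg: float = 3.0
    max_delay_ms: float = 300.0

    def __post_init__(self) -> None:
        if not (self.max_saccades > 0 and self.max_deviation_deg > 0 and self.max_delay_ms > 0):
            raise ConfigError("all decision thresholds must be strictly positive")


@dataclass(frozen=True)
class ParameterFlags:
    """Per-parameter abnormality flags (True = threshold exceeded)."""

    ros: bool
    deviation: bool
    delay: bool

    def any(self) -> bool:
        return self.ros or self.deviation or self.delay


@dataclass(frozen=True)
class EvaluationResult:
    label: str
    flags: ParameterFlags
    features: FeatureSet
    thresholds: DecisionThresholds

    def __post_init__(self) -> None:
        if (self.label == POSITIVE) != self.flags.any():
            raise ConfigError("label must be positive iff any flag is set")


def classify(
    features: FeatureSet, thresholds: DecisionThresholds = DecisionThresholds()
) -> EvaluationResult:
    """Apply the OR rule; the result keeps every flag so a clinician can see
    which parameter drove a positive."""
    for name in ("n_saccades", "deviation_deg", "delay_ms"):
        if getattr(features, name) is None:
            raise EOGError(f"cannot classify: feature '{name}' is missing")
    flags = ParameterFlags(
        ros=features.n_saccades > thresholds.max_saccades,
        deviation=abs(features.deviation_deg) > thresholds.max_deviation_deg,
        delay=features.delay_ms >= thresholds.max_delay_ms,
    )
    return EvaluationResult(
        label=POSITIVE if flags.any() else NEGATIVE,
        flags=flags,
        features=features,
        thresholds=thresholds,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with 'positive' meaning ataxia."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Screening metrics in percent; None where the denominator was zero."""

    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]
    accuracy_pct: Optional[float]


def compute_metrics(counts: ConfusionCounts, ndigits: int = 1) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total, each ×100 and rounded half-up to ``ndigits``.

    A zero denominator leaves just that metric undefined (None) instead of
    failing the whole computation.
    """
    if counts.total < 1:
        raise ConfigError("need at least one counted case")

    def pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, ndigits)

    return Metrics(
        sensitivity_pct=pct(counts.tp, counts.tp + counts.fn),
        specificity_pct=pct(counts.tn, counts.tn + counts.fp),
        accuracy_pct=pct(counts.tp + counts.tn, counts.total),
    )


def _as_binary(label: str, kind: str) -> bool:
    low = str(label).strip().lower()
    if low in _POSITIVE_LABELS:
        return True
    if low in _NEGATIVE_LABELS:
        return False
    raise EOGError(f"unknown {kind} label {label!r}")


def tabulate_confusion(
    predictions: Sequence[str], truths: Sequence[str]
) -> ConfusionCounts:
    """Count TP/FP/TN/FN for paired prediction / ground-truth labels.

    Predictions use positive/negative; truths may use ataxia/healthy (or the
    same vocabulary). Lists must be equal length.
    """
    if len(predictions) != len(truths):
        raise EOGError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    tp = fp = tn = fn = 0
    for pred, truth in zip(predictions, truths):
        p = _as_binary(pred, "prediction")
        t = _as_binary(truth, "truth")
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and not t:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
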