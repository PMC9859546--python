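"""Calibrating the failure-probability cutoff on labeled tasks.

The vertebral failure probability is a material quantity, not yet a verdict
about low-back-pain risk.  The cutoff that separates low- from high-risk
tasks is calibrated on a table of material-handling tasks, each with a
computed failure probability and an epidemiological low/high label (incidence
of low back pain).  The calibration sweeps candidate cutoffs and keeps the
one with the best overall classification accuracy.

Candidates are the midpoints between adjacent distinct probabilities (plus 0
and 1): with a strict ``probability > cutoff`` decision rule, accuracy is a
step function whose steps occur exactly at observed probabilities, so the
midpoint grid evaluates every achievable classification.  Ties in overall
accuracy prefer higher sensitivity (fewer missed high-risk tasks), then the
lower cutoff — both protective choices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RiskLabel",
    "LabeledTask",
    "CalibrationResult",
    "evaluate_threshold",
    "calibrate",
    "load_tasks_csv",
]


class RiskLabel(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class LabeledTask:
    """One material-handling task with its computed failure probability."""

    id: str
    failure_probability: float
    label: RiskLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", RiskLabel(self.label))
        if not 0.0 <= self.failure_probability <= 1.0:
            raise ValidationError(
                f"task {self.id!r}: failure probability must be in [0, 1] "
                f"(got {self.failure_probability:g})"
            )


@dataclass(frozen=True)
class CalibrationResult:
    """Cutoff plus its confusion matrix and accuracy decomposition.

    ``high_risk_accuracy`` is the sensitivity (high-risk tasks classified
    high), ``low_risk_accuracy`` the specificity.  A class-specific accuracy
    is ``None`` when that class is absent from the task list.
    """

    threshold: float
    overall_accuracy: float
    high_risk_accuracy: float | None
    low_risk_accuracy: float | None
    confusion: dict  # keys tp, fp, tn, fn

    def __post_init__(self) -> None:
        c = self.confusion
        total = c["tp"] + c["fp"] + c["tn"] + c["fn"]
        if total == 0 or abs(self.overall_accuracy - (c["tp"] + c["tn"]) / total) > 1e-12:
            raise ValidationError("overall accuracy inconsistent with confusion matrix")


def evaluate_threshold(
    tasks: list[LabeledTask], threshold: float, inclusive: bool = False
) -> CalibrationResult:
    """Classify every task at a fixed cutoff and score the result.

    Predicted high-risk iff ``failure_probability > threshold`` (or ``>=``
    when ``inclusive`` is set, for reproducing analyses that counted ties as
    exceedances).
    """
    if not tasks:
        raise ValidationError("task list is empty")
    probs = np.array([t.failure_probability for t in tasks])
    is_high = np.array([t.label is RiskLabel.HIGH for t in tasks])
    pred_high = probs >= threshold if inclusive else probs > threshold
    tp = int(np.sum(pred_high & is_high))
    fp = int(np.sum(pred_high & ~is_high))
    tn = int(np.sum(~pred_high & ~is_high))
    fn = int(np.sum(~pred_high & is_high))
    n_high, n_low = tp + fn, tn + fp
    return CalibrationResult(
        threshold=float(threshold),
        overall_accuracy=(tp + tn) / len(tasks),
        high_risk_accuracy=tp / n_high if n_high else None,
        low_risk_accuracy=tn / n_low if n_low else None,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def candidate_thresholds(tasks: list[LabeledTask]) -> np.ndarray:
    """Midpoints between adjacent distinct probabilities, plus 0 and 1."""
    uniq = np.unique([t.failure_probability for t in tasks])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate(([0.0], mids, [1.0])))


def calibrate(
    tasks: list[LabeledTask], inclusive: bool = False
) -> CalibrationResult:
    """Pick the cutoff with the best overall accuracy on the candidate grid.

    Ties are broken by (a) higher high-risk accuracy (sensitivity), then
    (b) the lowest cutoff.  The returned accuracy is by construction at
    least that of any user-supplied cutoff.
    """
    if not tasks:
        raise ValidationError("task list is empty")
    best: CalibrationResult | None = None
    for thr in candidate_thresholds(tasks):
        res = evaluate_threshold(tasks, float(thr), inclusive=inclusive)
        if best is None:
            best = res
            continue
        key_new = (res.overall_accuracy, res.high_risk_accuracy or 0.0, -res.threshold)
        key_old = (best.overall_accuracy, best.high_risk_accuracy or 0.0, -best.threshold)
        if key_new > key_old:
            best = res
    assert best is not None
    return best


def sweep(tasks: list[LabeledTask], inclusive: bool = False) -> pd.DataFrame:
    """Accuracy profile over the whole candidate grid (for reports/plots)."""
    rows = []
    for thr in candidate_thresholds(tasks):
        r = evaluate_threshold(tasks, float(thr), inclusive=inclusive)
        rows.append(
            {
                "threshold": r.threshold,
                "overall_accuracy": r.overall_accuracy,
                "high_risk_accuracy": r.high_risk_accuracy,
                "low_risk_accuracy": r.low_risk_accuracy,
                **r.confusion,
            }
        )
    return pd.DataFrame(rows)


def load_tasks_csv(path: str | Path) -> list[LabeledTask]:
    """Read a labeled task table: columns ``id,failure_probability,label``."""
    df = pd.read_csv(path)
    required = {"id", "failure_probability", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {', '.join(sorted(missing))}"
        )
    return [
        LabeledTask(str(r.id), float(r.failure_probability), RiskLabel(str(r.label)))
        for r in df.itertuples(index=False)
    ]
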