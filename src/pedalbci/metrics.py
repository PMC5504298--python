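"""Evaluation metrics: TPR, FP/min, Acc, FPR and the weighted discriminator (WD).

With detection counts per test split,

.. math::

    TPR &= \\frac{\\text{true detections}}{\\text{true events}} \\\\
    FP/min &= \\frac{\\text{false detections}}{\\text{rest time in minutes}} \\\\
    Acc &= \\frac{\\text{true detections}}{\\text{total detections}}

the weighted discriminator combines all three into one model-comparison
number in [-1, 1]:

.. math::

    WD = 0.4\\,TPR + 0.6\\,Acc - 1.0\\,FPR, \\qquad
    FPR = (FP/min) \\times d_{FP}

where the duration of a single false positive, ``d_FP``, is the class
window length (2 or 4 s) for the offline analysis and 1 s (five
consecutive 200 ms epoch decisions) for the pseudo-online analysis, in
minutes.  TPR and Acc enter as fractions; Acc is 0 by convention when
there are no detections at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import ValidationError

W_TPR = 0.4
W_ACC = 0.6
W_FPR = 1.0


@dataclass(frozen=True)
class WDWeights:
    """Weights of the weighted discriminator plus the FP duration to use."""

    w_tpr: float = W_TPR
    w_acc: float = W_ACC
    w_fpr: float = W_FPR
    fp_duration_min: float = 1.0 / 60.0

    @staticmethod
    def for_mode(mode: Literal["offline", "pseudo-online"], window_type: str = "4s") -> "WDWeights":
        if mode == "offline":
            length = {"2s": 2.0, "4s": 4.0}.get(window_type)
            if length is None:
                raise ValidationError(f"unknown window type {window_type!r}")
            return WDWeights(fp_duration_min=length / 60.0)
        if mode == "pseudo-online":
            return WDWeights(fp_duration_min=1.0 / 60.0)
        raise ValidationError(f"unknown analysis mode {mode!r}")


@dataclass
class EvaluationResult:
    """Counts and metrics for one model/test split."""

    n_true_events: int
    n_true_detections: int
    n_false_detections: int
    rest_time_min: float
    tpr: float
    fp_per_min: float
    acc: float
    fpr: float
    wd: float

    @staticmethod
    def from_counts(
        n_true_detections: int,
        n_true_events: int,
        n_false_detections: int,
        rest_time_min: float,
        weights: WDWeights,
    ) -> "EvaluationResult":
        tpr, fp_per_min, acc = compute_counts_metrics(
            n_true_detections, n_true_events, n_false_detections, rest_time_min
        )
        wd = compute_wd(tpr, acc, fp_per_min, weights)
        return EvaluationResult(
            n_true_events=n_true_events,
            n_true_detections=n_true_detections,
            n_false_detections=n_false_detections,
            rest_time_min=rest_time_min,
            tpr=tpr,
            fp_per_min=fp_per_min,
            acc=acc,
            fpr=fp_per_min * weights.fp_duration_min,
            wd=wd,
        )

    def as_dict(self) -> dict:
        return {
            "tpr_pct": 100.0 * self.tpr,
            "fp_per_min": self.fp_per_min,
            "acc_pct": 100.0 * self.acc,
            "fpr": self.fpr,
            "wd": self.wd,
        }


def compute_counts_metrics(
    n_true_det: int, n_true_events: int, n_false_det: int, rest_time_min: float
) -> tuple[float, float, float]:
    """(TPR, FP/min, Acc) from raw counts; Acc = 0 when nothing was detected."""
    if min(n_true_det, n_true_events, n_false_det) < 0:
        raise ValidationError("detection counts must be nonnegative")
    if n_true_events < 1:
        raise ValidationError("at least one true event is required")
    if rest_time_min <= 0:
        raise ValidationError("rest time must be positive")
    tpr = n_true_det / n_true_events
    fp_per_min = n_false_det / rest_time_min
    total = n_true_det + n_false_det
    acc = n_true_det / total if total > 0 else 0.0
    return tpr, fp_per_min, acc


def compute_wd(tpr: float, acc: float, fp_per_min: float, weights: WDWeights) -> float:
    """Weighted discriminator from TPR/Acc fractions and FP/min."""
    if not all(math.isfinite(v) for v in (tpr, acc, fp_per_min)):
        raise ValidationError("metrics must be finite")
    fpr = fp_per_min * weights.fp_duration_min
    return weights.w_tpr * tpr + weights.w_acc * acc - weights.w_fpr * fpr


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as in the published tables."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
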