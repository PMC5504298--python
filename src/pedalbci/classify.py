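"""RBF-SVM model, majority vote, voting queue, and the two evaluation schemes.

Offline: leave-one-trial-out cross-validation; each test class window's
epoch predictions are grouped (16 per 4 s window, 6 per 2 s window) and
reduced by a majority vote (ties -> 0); metrics are averaged over the
folds.  Pseudo-online: the model is trained on the first trials only and
every 200 ms-stepped epoch of each test cycle is classified in temporal
order; a detection fires after 5 consecutive positive epoch predictions
(the counter resets after firing) and is true iff its timestamp lies in a
start class window, with at most one true detection counted per window.

Hyperparameters (unstated in the protocol, recorded in the model): C = 1,
RBF gamma = 1/(n_features x feature variance) (scikit-learn's "scale"),
features z-scored with training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .features import FeatureVector, OptimalFrequencies
from .metrics import EvaluationResult, WDWeights, compute_wd
from .montage import ElectrodeConfiguration
from .windows import ClassWindow

LABEL_CODES = {"rest": 0, "start": 1}

#: Consecutive positive epoch predictions required to fire a detection.
VOTING_QUEUE_LENGTH = 5


@dataclass
class TrainedModel:
    """Fitted classifier plus the feature-side state it depends on."""

    estimator: Pipeline
    algorithm: str
    config: ElectrodeConfiguration | None = None
    optimal_frequencies: OptimalFrequencies | None = None
    window_type: str = "4s"
    hyperparameters: dict | None = None

    def predict(self, X: np.ndarray | Sequence[FeatureVector]) -> np.ndarray:
        return self.estimator.predict(_as_matrix(X))


@dataclass(frozen=True)
class DetectionEvent:
    """One voting-queue detection: end time of the 5th consecutive positive epoch."""

    time: float
    is_true: bool
    cycle_index: int = -1


def _as_matrix(features: np.ndarray | Sequence[FeatureVector]) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return features
    return np.vstack([f.values for f in features])


def _as_labels(labels: Sequence) -> np.ndarray:
    return np.asarray([LABEL_CODES.get(l, l) for l in labels], dtype=int)


def make_estimator(C: float = 1.0, gamma: str | float = "scale") -> Pipeline:
    return Pipeline(
        [("scaler", StandardScaler()), ("svc", SVC(C=C, kernel="rbf", gamma=gamma))]
    )


def train_model(
    features: np.ndarray | Sequence[FeatureVector],
    labels: Sequence,
    algorithm: str = "",
    config: ElectrodeConfiguration | None = None,
    optimal_frequencies: OptimalFrequencies | None = None,
    window_type: str = "4s",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> TrainedModel:
    """Fit the standardized RBF-SVM on labeled feature vectors.

    Deterministic given identical inputs and hyperparameters.
    """
    X = _as_matrix(features)
    y = _as_labels(labels)
    if len(X) != len(y):
        raise ValidationError(f"{len(X)} feature vectors but {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    est = make_estimator(C=C, gamma=gamma)
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        algorithm=algorithm,
        config=config,
        optimal_frequencies=optimal_frequencies,
        window_type=window_type,
        hyperparameters={"C": C, "gamma": gamma, "scaler": "zscore"},
    )


def majority_vote(predictions: Sequence[int]) -> int:
    """1 iff strictly more 1s than 0s; ties resolve to 0."""
    preds = np.asarray(predictions)
    if preds.size == 0:
        raise ValidationError("majority vote over an empty prediction list")
    ones = int(preds.sum())
    return 1 if ones > preds.size - ones else 0


def run_voting_queue(predictions: Sequence[int], n_required: int = VOTING_QUEUE_LENGTH) -> list[int]:
    """Indices at which a detection fires (5th consecutive 1; counter resets)."""
    fired = []
    counter = 0
    for i, p in enumerate(predictions):
        counter = counter + 1 if p == 1 else 0
        if counter >= n_required:
            fired.append(i)
            counter = 0
    return fired


def offline_cross_validation(
    folds: Iterable[
        tuple[np.ndarray, np.ndarray, list[tuple[str, np.ndarray]]]
    ],
    weights: WDWeights,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> tuple[EvaluationResult, list[EvaluationResult]]:
    """Cross-validation engine over prepared feature folds.

    Each fold supplies ``(train_X, train_y, test_groups)`` where
    ``test_groups`` is one ``(label, X)`` entry per test class window.  A
    fold's decision per group is the majority vote of the group's epoch
    predictions; its rest time is the summed rest-window duration.  The
    aggregate averages TPR, FP/min and Acc across folds and recomputes WD
    from the averages.
    """
    per_fold: list[EvaluationResult] = []
    for train_X, train_y, groups in folds:
        model = train_model(train_X, train_y, C=C, gamma=gamma)
        true_events = true_det = false_det = n_rest = 0
        for label, X in groups:
            decision = majority_vote(model.predict(X))
            if LABEL_CODES[label] == 1:
                true_events += 1
                true_det += decision
            else:
                n_rest += 1
                false_det += decision
        rest_time_min = n_rest * weights.fp_duration_min
        per_fold.append(
            EvaluationResult.from_counts(true_det, true_events, false_det, rest_time_min, weights)
        )
    if not per_fold:
        raise ValidationError("cross-validation requires at least one fold")
    return aggregate_results(per_fold, weights), per_fold


def aggregate_results(results: list[EvaluationResult], weights: WDWeights) -> EvaluationResult:
    """Average TPR/FP-min/Acc over splits; WD recomputed from the averages."""
    tpr = float(np.mean([r.tpr for r in results]))
    fp = float(np.mean([r.fp_per_min for r in results]))
    acc = float(np.mean([r.acc for r in results]))
    return EvaluationResult(
        n_true_events=sum(r.n_true_events for r in results),
        n_true_detections=sum(r.n_true_detections for r in results),
        n_false_detections=sum(r.n_false_detections for r in results),
        rest_time_min=sum(r.rest_time_min for r in results),
        tpr=tpr,
        fp_per_min=fp,
        acc=acc,
        fpr=fp * weights.fp_duration_min,
        wd=compute_wd(tpr, acc, fp, weights),
    )


def score_stream(
    epoch_end_times: np.ndarray,
    predictions: np.ndarray,
    start_windows: list[ClassWindow],
    n_required: int = VOTING_QUEUE_LENGTH,
) -> tuple[list[DetectionEvent], int, int]:
    """Apply the voting queue to one temporal prediction stream.

    Returns the detection events plus (n_true_detections,
    n_false_detections); multiple true detections inside one start window
    count once.
    """
    events: list[DetectionEvent] = []
    credited: set[int] = set()
    n_true = n_false = 0
    for i in run_voting_queue(predictions, n_required):
        t = float(epoch_end_times[i])
        hit = next((w for w in start_windows if w.contains(t)), None)
        if hit is not None:
            events.append(DetectionEvent(t, True, hit.cycle_index))
            if hit.cycle_index not in credited:
                credited.add(hit.cycle_index)
                n_true += 1
        else:
            events.append(DetectionEvent(t, False))
            n_false += 1
    return events, n_true, n_false


# Session-level wrappers live in pipeline.py; re-exported here for the
# module surface.
def evaluate_offline(session, algorithm, config, window_type="4s", **kwargs):
    """Leave-one-trial-out offline evaluation of one (algorithm, E.C.) pair."""
    from .pipeline import SessionEvaluator

    ev = SessionEvaluator(session, window_type=window_type, **kwargs)
    return ev.offline(algorithm, config)


def evaluate_pseudo_online(session, algorithm, config, window_type="4s", **kwargs):
    """Train on the first trials, stream the rest through the voting queue.

    Returns ``(detections, aggregate_result, per_trial_results)``.
    """
    from .pipeline import SessionEvaluator

    ev = SessionEvaluator(session, window_type=window_type, **kwargs)
    return ev.pseudo_online(algorithm, config)
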