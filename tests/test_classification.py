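"""SVM training, majority vote, voting queue and cross-validation mechanics."""

import numpy as np
import pytest

from pedalbci.classify import (
    majority_vote,
    offline_cross_validation,
    run_voting_queue,
    score_stream,
    train_model,
)
from pedalbci.errors import ValidationError
from pedalbci.metrics import WDWeights
from pedalbci.windows import ClassWindow


def _separable(rng, n=40):
    X0 = rng.normal([0, 0], 0.3, (n, 2))
    X1 = rng.normal([4, 4], 0.3, (n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestTrainModel:
    def test_separable_training_accuracy_is_perfect(self, rng):
        X, y = _separable(rng)
        model = train_model(X, y)
        assert (model.predict(X) == y).all()

    def test_deterministic_given_identical_inputs(self, rng):
        X, y = _separable(rng)
        probe = rng.normal(2, 2, (30, 2))
        p1 = train_model(X, y).predict(probe)
        p2 = train_model(X, y).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_label_length_mismatch_rejected(self, rng):
        X, y = _separable(rng)
        with pytest.raises(ValidationError):
            train_model(X, y[:-1])

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValidationError):
            train_model(X, [0] * 10)


class TestMajorityVote:
    def test_strict_majority_wins(self):
        assert majority_vote([1] * 9 + [0] * 7) == 1

    def test_tie_of_sixteen_resolves_to_rest(self):
        assert majority_vote([1] * 8 + [0] * 8) == 0

    def test_tie_of_six_resolves_to_rest(self):
        assert majority_vote([1, 0, 1, 0, 1, 0]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([])


class TestVotingQueue:
    def test_five_consecutive_fire_once(self):
        assert run_voting_queue([0, 1, 1, 1, 1, 1, 0]) == [5]

    def test_counter_resets_after_firing(self):
        assert run_voting_queue([1] * 10) == [4, 9]

    def test_broken_runs_never_fire(self):
        assert run_voting_queue([1, 1, 1, 1, 0, 1, 1, 1, 1, 0]) == []


class TestScoreStream:
    def test_detection_timestamp_and_truth(self):
        ends = np.arange(10) * 0.2 + 1.0
        preds = np.array([0, 1, 1, 1, 1, 1, 0, 0, 0, 0])
        window = ClassWindow("start", 1.5, 3.0, cycle_index=3)
        events, n_true, n_false = score_stream(ends, preds, [window])
        assert len(events) == 1
        assert events[0].time == pytest.approx(2.0)
        assert events[0].is_true and events[0].cycle_index == 3
        assert (n_true, n_false) == (1, 0)

    def test_repeated_hits_in_one_window_count_once(self):
        ends = np.arange(15) * 0.2 + 1.0
        preds = np.ones(15, dtype=int)
        window = ClassWindow("start", 0.0, 10.0, cycle_index=0)
        events, n_true, n_false = score_stream(ends, preds, [window])
        assert len(events) == 3  # fires at epochs 5, 10, 15
        assert (n_true, n_false) == (1, 0)

    def test_detection_outside_window_is_false_positive(self):
        ends = np.arange(6) * 0.2 + 1.0
        preds = np.array([1, 1, 1, 1, 1, 0])
        events, n_true, n_false = score_stream(ends, preds, [ClassWindow("start", 5.0, 9.0)])
        assert (n_true, n_false) == (0, 1)


def _oracle_folds(rng, n_trials=4, cycles=2, epochs=16, separation=4.0, shuffle_labels=False):
    """Synthetic feature folds: rest/start clusters, optionally label-shuffled."""
    all_groups = []
    for _ in range(n_trials):
        trial = []
        for _ in range(cycles):
            rest = rng.normal(0, 0.4, (epochs, 2))
            start = rng.normal(separation, 0.4, (epochs, 2))
            trial.append((rest, start))
        all_groups.append(trial)
    for test_idx in range(n_trials):
        X_parts, y_parts = [], []
        for i, trial in enumerate(all_groups):
            if i == test_idx:
                continue
            for rest, start in trial:
                X_parts += [rest, start]
                y_parts += [0] * epochs + [1] * epochs
        X = np.vstack(X_parts)
        y = np.array(y_parts)
        if shuffle_labels:
            y = rng.permutation(y)
        groups = []
        for rest, start in all_groups[test_idx]:
            groups.append(("rest", rest))
            groups.append(("start", start))
        yield X, y, groups


def test_offline_cv_perfect_on_separable_features(rng):
    weights = WDWeights.for_mode("offline", "4s")
    agg, per_fold = offline_cross_validation(_oracle_folds(rng), weights)
    assert len(per_fold) == 4  # every trial tested exactly once
    assert agg.n_true_events == 4 * 2
    assert agg.tpr == 1.0 and agg.acc == 1.0 and agg.fp_per_min == 0.0
    assert agg.wd == pytest.approx(1.0)


def test_offline_cv_shuffled_labels_give_chance_tpr():
    # Monte-Carlo null over >= 20 seeds: detection rate on start windows
    # should hover around 50% (the tie->0 rule biases it slightly low).
    weights = WDWeights.for_mode("offline", "4s")
    tprs = []
    for seed in range(24):
        rng = np.random.default_rng(seed)
        agg, _ = offline_cross_validation(
            _oracle_folds(rng, shuffle_labels=True), weights
        )
        tprs.append(agg.tpr)
    assert np.mean(tprs) == pytest.approx(0.5, abs=0.1)


def test_offline_cv_no_folds_rejected():
    with pytest.raises(ValidationError):
        offline_cross_validation(iter([]), WDWeights.for_mode("offline", "4s"))
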