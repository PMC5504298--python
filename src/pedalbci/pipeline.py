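"""Session-level evaluation: single combinations, full WD grids, cohort studies.

:class:`SessionEvaluator` prepares a session once (class windows, epoch
slicing, per-epoch preprocessing, spectral primitives) and then evaluates
any (algorithm, electrode configuration) pair in either analysis mode.
Spectral primitives are computed for the full 32-channel montage so that
the eight configurations only differ by column selection, which makes the
8 x 5 WD grid cheap relative to the classifier fits.

Algorithm D's optimal frequencies are refit for every training split
(per fold offline, on the training trials pseudo-online) from cached
per-trial class-mean spectra, so no training-set information leaks into
test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import (
    DetectionEvent,
    TrainedModel,
    aggregate_results,
    offline_cross_validation,
    score_stream,
    train_model,
)
from .data_model import Session
from .errors import ValidationError
from .features import (
    ALGORITHMS,
    FEATURES_PER_CHANNEL,
    OptimalFrequencies,
    amplitude_spectrum,
    periodogram_psd,
)
from .metrics import EvaluationResult, WDWeights
from .montage import DEFAULT_CONFIGS, ElectrodeConfiguration, get_configuration
from .preprocess import FilterSpec, preprocess_array
from .selection import WDMatrix
from .windows import (
    WINDOW_LENGTHS_S,
    EpochingParams,
    build_class_windows,
    epoch_start_indices,
)

# Extended 0.5 Hz band kept for algorithm D: 7.0 .. 29.0 Hz (optimal
# frequency 8-28 Hz plus the +/- 1 Hz feature margin).
_EXT_LO_BIN = 14
_EXT_HI_BIN = 58
_BAND_IN_EXT = slice(2, 43)  # 8.0 .. 28.0 Hz within the extended band
_HALF_BINS = 2  # +/- 1 Hz at 0.5 Hz resolution


@dataclass
class _CycleData:
    trial: int
    row: int
    onset: float
    interval: tuple[float, float]
    rest: dict[str, np.ndarray] | None = None
    start: dict[str, np.ndarray] | None = None
    stream_ends: np.ndarray | None = None
    stream: dict[str, np.ndarray] | None = None


class SessionEvaluator:
    """Prepares one session and evaluates (algorithm, configuration) pairs."""

    def __init__(
        self,
        session: Session,
        window_type: str = "4s",
        epoching: EpochingParams | None = None,
        filter_spec: FilterSpec | None = None,
        configs: dict[int, ElectrodeConfiguration] | None = None,
        train_trials: int = 10,
        svm_c: float = 1.0,
        svm_gamma: str | float = "scale",
    ) -> None:
        if window_type not in WINDOW_LENGTHS_S:
            raise ValidationError(f"unknown window type {window_type!r}")
        self.session = session
        self.window_type = window_type
        self.epoching = epoching or EpochingParams(window_type=window_type)
        self.filter_spec = filter_spec or FilterSpec()
        self.configs = configs if configs is not None else DEFAULT_CONFIGS
        self.train_trials = train_trials
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self.fs = session.eeg.sampling_rate
        self.channel_names = list(session.eeg.channel_names)
        self._ch_index = {c: i for i, c in enumerate(self.channel_names)}

        intervals = session.cycle_intervals()
        active = session.events.active()
        self.cycles: list[_CycleData] = [
            _CycleData(
                trial=int(r["trial"]),
                row=int(idx),
                onset=float(r["real_start_time_s"]),
                interval=intervals[int(idx)],
            )
            for idx, r in active.iterrows()
        ]
        if not self.cycles:
            raise ValidationError("session has no usable (non-discarded) cycles")
        self.trials = sorted({c.trial for c in self.cycles})
        self._features: dict[str, dict[int, dict[str, np.ndarray]]] = {}
        self._stream_features: dict[str, dict[int, np.ndarray]] = {}
        self._class_prims_done = False
        self._streams_done = False
        self._d_sums: dict | None = None

    # ---------------- preparation ----------------

    def _epoch_array(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """(epochs x channels x samples, epoch end times) for [t0, t1)."""
        eeg = self.session.eeg
        starts = epoch_start_indices(
            t0 - eeg.start_time, t1 - eeg.start_time, self.fs,
            self.epoching.epoch_length, self.epoching.shift,
        )
        n_epoch = int(round(self.epoching.epoch_length * self.fs))
        data = np.stack([eeg.samples[:, i : i + n_epoch] for i in starts]) if len(starts) else (
            np.empty((0, eeg.n_channels, n_epoch))
        )
        ends = eeg.start_time + (starts + n_epoch) / self.fs
        return data, ends

    def _primitives(self, data: np.ndarray) -> dict[str, np.ndarray]:
        """Per-epoch, per-channel spectral primitives after preprocessing."""
        if data.shape[0] == 0:
            return {
                "P1": np.empty((0, data.shape[1], 51), dtype=np.float32),
                "M1": np.empty((0, data.shape[1], 51), dtype=np.float32),
                "P05": np.empty((0, data.shape[1], _EXT_HI_BIN - _EXT_LO_BIN + 1), dtype=np.float32),
            }
        clean = preprocess_array(np.asarray(data, dtype=np.float64), self.fs, self.filter_spec)
        p1 = periodogram_psd(clean, self.fs, 1.0).power[..., :51]
        m1 = amplitude_spectrum(clean, self.fs, 1.0).power[..., :51]
        p05 = periodogram_psd(clean, self.fs, 0.5).power[..., _EXT_LO_BIN : _EXT_HI_BIN + 1]
        return {
            "P1": p1.astype(np.float32),
            "M1": m1.astype(np.float32),
            "P05": p05.astype(np.float32),
        }

    def _prepare_class_epochs(self) -> None:
        if self._class_prims_done:
            return
        for cyc in self.cycles:
            rest_w, start_w = build_class_windows(
                cyc.onset, self.window_type, cycle_index=cyc.row, cycle_start=cyc.interval[0]
            )
            rest_data, _ = self._epoch_array(rest_w.t0, rest_w.t1)
            start_data, _ = self._epoch_array(start_w.t0, start_w.t1)
            cyc.rest = self._primitives(rest_data)
            cyc.start = self._primitives(start_data)
        self._class_prims_done = True

    def _prepare_streams(self) -> None:
        if self._streams_done:
            return
        test_trials = set(self._test_trials())
        for cyc in self.cycles:
            if cyc.trial not in test_trials:
                continue
            data, ends = self._epoch_array(*cyc.interval)
            cyc.stream = self._primitives(data)
            cyc.stream_ends = ends
        self._streams_done = True

    def _test_trials(self) -> list[int]:
        if self.train_trials >= len(self.trials):
            raise ValidationError(
                f"pseudo-online needs test trials: {len(self.trials)} trials, "
                f"{self.train_trials} used for training"
            )
        return self.trials[self.train_trials :]

    # ---------------- feature assembly ----------------

    def _config_columns(self, config: ElectrodeConfiguration, algorithm: str) -> list[int]:
        k = FEATURES_PER_CHANNEL[algorithm]
        cols = []
        for ch in config.channels:
            if ch not in self._ch_index:
                raise ValidationError(f"session is missing channel {ch} of E.C. {config.config_id}")
            i = self._ch_index[ch]
            cols.extend(range(i * k, i * k + k))
        return cols

    @staticmethod
    def _assemble(prims: dict[str, np.ndarray], algorithm: str,
                  opt_centers: np.ndarray | None = None) -> np.ndarray:
        """Full-montage feature matrix (epochs x 32*k) from primitives."""
        p1, m1, p05 = prims["P1"], prims["M1"], prims["P05"]
        n, nch = p1.shape[0], p1.shape[1]
        if algorithm == "A":
            out = p1[..., 18:29].mean(axis=-1)
        elif algorithm == "B":
            out = np.linalg.norm(m1, axis=-1)
        elif algorithm == "C":
            out = np.stack(
                [p1[..., 1:5].mean(-1), p1[..., 8:13].mean(-1), p1[..., 13:29].mean(-1)],
                axis=-1,
            )
        elif algorithm == "E":
            out = np.stack(
                [m1[..., 8:13].sum(-1), m1[..., 13:25].sum(-1), m1[..., 25:31].sum(-1)],
                axis=-1,
            )
        elif algorithm == "D":
            if opt_centers is None:
                raise ValidationError("algorithm D requires fitted optimal frequencies")
            idx = opt_centers[:, None] + np.arange(-_HALF_BINS, _HALF_BINS + 1)[None, :]
            take = np.take_along_axis(p05, np.broadcast_to(idx, (n, nch, idx.shape[1])), axis=-1)
            out = take.mean(axis=-1)
        else:
            raise ValidationError(f"unknown feature algorithm {algorithm!r}")
        return out.reshape(n, -1).astype(np.float64)

    def _class_features(self, algorithm: str) -> dict[int, dict[str, np.ndarray]]:
        """Cached full-montage class-window features per cycle (A/B/C/E)."""
        self._prepare_class_epochs()
        if algorithm not in self._features:
            self._features[algorithm] = {
                cyc.row: {
                    "rest": self._assemble(cyc.rest, algorithm),
                    "start": self._assemble(cyc.start, algorithm),
                }
                for cyc in self.cycles
            }
        return self._features[algorithm]

    # ---------------- algorithm D frequency fitting ----------------

    def _class_band_sums(self) -> dict:
        """Per-trial sums of the 8-28 Hz class spectra, for cheap refits."""
        if self._d_sums is not None:
            return self._d_sums
        self._prepare_class_epochs()
        nch = len(self.channel_names)
        nb = _BAND_IN_EXT.stop - _BAND_IN_EXT.start
        sums = {t: {"rest": np.zeros((nch, nb)), "start": np.zeros((nch, nb)),
                    "n_rest": 0, "n_start": 0} for t in self.trials}
        for cyc in self.cycles:
            s = sums[cyc.trial]
            s["rest"] += cyc.rest["P05"][..., _BAND_IN_EXT].sum(axis=0)
            s["start"] += cyc.start["P05"][..., _BAND_IN_EXT].sum(axis=0)
            s["n_rest"] += cyc.rest["P05"].shape[0]
            s["n_start"] += cyc.start["P05"].shape[0]
        self._d_sums = sums
        return sums

    def _fit_opt_centers(self, train_trials: list[int]) -> np.ndarray:
        """Optimal-frequency bin centers (indices into the extended band)."""
        sums = self._class_band_sums()
        rest = sum(sums[t]["rest"] for t in train_trials)
        start = sum(sums[t]["start"] for t in train_trials)
        n_rest = sum(sums[t]["n_rest"] for t in train_trials)
        n_start = sum(sums[t]["n_start"] for t in train_trials)
        if n_rest == 0 or n_start == 0:
            raise ValidationError("both classes must be non-empty to fit algorithm D")

        def norm(mean: np.ndarray) -> np.ndarray:
            tot = mean.sum(axis=-1, keepdims=True)
            return np.where(tot > 0, mean / np.where(tot > 0, tot, 1.0), 0.0)

        diff = np.abs(norm(start / n_start) - norm(rest / n_rest))
        return np.argmax(diff, axis=-1) + _BAND_IN_EXT.start

    def optimal_frequencies(self, train_trials: list[int] | None = None) -> OptimalFrequencies:
        """Fitted per-channel optimal frequencies (Hz) on the given trials."""
        trials = train_trials if train_trials is not None else self.trials
        centers = self._fit_opt_centers(trials)
        freqs = 7.0 + 0.5 * (centers - 0.0)  # extended band starts at 7.0 Hz
        return OptimalFrequencies(list(self.channel_names), freqs)

    # ---------------- evaluation ----------------

    def offline(self, algorithm: str, config: int | ElectrodeConfiguration
                ) -> EvaluationResult:
        """Leave-one-trial-out evaluation; metrics averaged over the folds."""
        result, _ = self.offline_detailed(algorithm, config)
        return result

    def offline_detailed(self, algorithm: str, config: int | ElectrodeConfiguration
                         ) -> tuple[EvaluationResult, list[EvaluationResult]]:
        config = self._resolve_config(config)
        if algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown feature algorithm {algorithm!r}")
        weights = WDWeights.for_mode("offline", self.window_type)
        cols = self._config_columns(config, algorithm)
        by_trial: dict[int, list[_CycleData]] = {}
        for cyc in self.cycles:
            by_trial.setdefault(cyc.trial, []).append(cyc)

        def folds():
            for test_trial in self.trials:
                train_trials = [t for t in self.trials if t != test_trial]
                feats = self._fold_features(algorithm, train_trials)
                train_X, train_y = [], []
                for t in train_trials:
                    for cyc in by_trial[t]:
                        train_X.append(feats[cyc.row]["rest"][:, cols])
                        train_y.extend([0] * feats[cyc.row]["rest"].shape[0])
                        train_X.append(feats[cyc.row]["start"][:, cols])
                        train_y.extend([1] * feats[cyc.row]["start"].shape[0])
                groups = []
                for cyc in by_trial[test_trial]:
                    groups.append(("rest", feats[cyc.row]["rest"][:, cols]))
                    groups.append(("start", feats[cyc.row]["start"][:, cols]))
                yield np.vstack(train_X), np.asarray(train_y), groups

        return offline_cross_validation(folds(), weights, C=self.svm_c, gamma=self.svm_gamma)

    def _fold_features(self, algorithm: str, train_trials: list[int]
                       ) -> dict[int, dict[str, np.ndarray]]:
        if algorithm != "D":
            return self._class_features(algorithm)
        centers = self._fit_opt_centers(train_trials)
        key = f"D:{tuple(train_trials)}"
        if key not in self._features:
            self._prepare_class_epochs()
            self._features[key] = {
                cyc.row: {
                    "rest": self._assemble(cyc.rest, "D", centers),
                    "start": self._assemble(cyc.start, "D", centers),
                }
                for cyc in self.cycles
            }
        return self._features[key]

    def pseudo_online(self, algorithm: str, config: int | ElectrodeConfiguration
                      ) -> tuple[list[DetectionEvent], EvaluationResult, list[EvaluationResult]]:
        """Train on the first trials; stream test cycles through the voting queue."""
        config = self._resolve_config(config)
        weights = WDWeights.for_mode("pseudo-online")
        train_trials = self.trials[: self.train_trials]
        test_trials = self._test_trials()
        cols = self._config_columns(config, algorithm)

        feats = self._fold_features(algorithm, train_trials)
        train_X, train_y = [], []
        optimal = None
        if algorithm == "D":
            optimal = self.optimal_frequencies(train_trials)
        for cyc in self.cycles:
            if cyc.trial not in train_trials:
                continue
            train_X.append(feats[cyc.row]["rest"][:, cols])
            train_y.extend([0] * feats[cyc.row]["rest"].shape[0])
            train_X.append(feats[cyc.row]["start"][:, cols])
            train_y.extend([1] * feats[cyc.row]["start"].shape[0])
        model = train_model(
            np.vstack(train_X), train_y, algorithm=algorithm, config=config,
            optimal_frequencies=optimal, window_type=self.window_type,
            C=self.svm_c, gamma=self.svm_gamma,
        )

        self._prepare_streams()
        centers = self._fit_opt_centers(train_trials) if algorithm == "D" else None
        window_len = WINDOW_LENGTHS_S[self.window_type]
        detections: list[DetectionEvent] = []
        per_trial: list[EvaluationResult] = []
        for trial in test_trials:
            n_true = n_false = n_events = 0
            rest_time_s = 0.0
            for cyc in self.cycles:
                if cyc.trial != trial:
                    continue
                _, start_w = build_class_windows(cyc.onset, self.window_type, cycle_index=cyc.row)
                stream_X = self._assemble(cyc.stream, algorithm, centers)[:, cols]
                preds = model.predict(stream_X)
                events, t_true, t_false = score_stream(cyc.stream_ends, preds, [start_w])
                detections.extend(events)
                n_true += t_true
                n_false += t_false
                n_events += 1
                rest_time_s += (cyc.interval[1] - cyc.interval[0]) - window_len
            per_trial.append(
                EvaluationResult.from_counts(n_true, n_events, n_false, rest_time_s / 60.0, weights)
            )
        return detections, aggregate_results(per_trial, weights), per_trial

    def _resolve_config(self, config: int | ElectrodeConfiguration) -> ElectrodeConfiguration:
        if isinstance(config, ElectrodeConfiguration):
            return config
        return get_configuration(config, self.configs)

    # ---------------- grids ----------------

    def wd_matrix(self, mode: str, algorithms: tuple[str, ...] = ALGORITHMS
                  ) -> tuple[WDMatrix, dict[tuple[int, str], list[float]]]:
        """WD over all configurations x algorithms for one analysis mode.

        Returns the matrix plus, for pseudo-online, the per-test-trial WD
        values of each cell (empty lists offline).
        """
        if mode not in ("offline", "pseudo-online"):
            raise ValidationError(f"unknown analysis mode {mode!r}")
        config_ids = sorted(self.configs)
        values = pd.DataFrame(index=config_ids, columns=list(algorithms), dtype=float)
        per_trial_wd: dict[tuple[int, str], list[float]] = {}
        for alg in algorithms:
            for cid in config_ids:
                if mode == "offline":
                    res = self.offline(alg, cid)
                    per_trial_wd[(cid, alg)] = []
                else:
                    _, res, per_trial = self.pseudo_online(alg, cid)
                    per_trial_wd[(cid, alg)] = [r.wd for r in per_trial]
                values.loc[cid, alg] = res.wd
        matrix = WDMatrix(
            subject_id=self.session.subject_id, mode=mode,
            window_type=self.window_type, values=values,
        )
        return matrix, per_trial_wd
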