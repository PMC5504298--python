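"""Feature algorithms A-E and algorithm D's optimal-frequency fit."""

import numpy as np
import pytest

from pedalbci.errors import ValidationError
from pedalbci.features import (
    FEATURES_PER_CHANNEL,
    OPTIMAL_FREQ_GRID,
    OptimalFrequencies,
    extract_features,
    fit_optimal_frequencies,
)
from pedalbci.windows import Epoch

FS = 500.0
T = np.arange(500) / FS
NAMES = ["C3", "C1", "CZ", "C2", "C4"]


def _epoch(data, names=NAMES):
    return Epoch(start_time=0.0, data=data, channel_names=list(names), sampling_rate=FS)


def _aux(freq=10.0, names=NAMES):
    return OptimalFrequencies(list(names), np.full(len(names), freq))


@pytest.mark.parametrize("algorithm,k", FEATURES_PER_CHANNEL.items())
def test_feature_length_contract(rng, algorithm, k):
    epoch = _epoch(rng.normal(0, 1, (5, 500)))
    fv = extract_features(epoch, algorithm, aux=_aux())
    assert fv.values.shape == (5 * k,)


def test_band_power_matches_periodogram_oracle():
    # independent oracle: raw-DFT periodogram, one-sided, mean over 18-28 Hz
    a = 7.0
    sig = a * np.sin(2 * np.pi * 20.0 * T)
    spec = np.abs(np.fft.rfft(sig)) ** 2 / (FS * len(sig))
    spec[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(len(sig), 1 / FS)
    oracle = spec[(freqs >= 18) & (freqs <= 28)].mean()

    fv = extract_features(_epoch(np.tile(sig, (5, 1))), "A")
    np.testing.assert_allclose(fv.values, oracle, rtol=1e-9)


def test_zero_signal_gives_zero_features():
    epoch = _epoch(np.zeros((5, 500)))
    for alg in "ABCDE":
        fv = extract_features(epoch, alg, aux=_aux())
        np.testing.assert_array_equal(fv.values, 0.0)


@pytest.mark.parametrize("algorithm,exponent", [("A", 2), ("B", 1), ("C", 2), ("D", 2), ("E", 1)])
def test_scale_covariance(rng, algorithm, exponent):
    data = rng.normal(0, 1, (5, 500))
    base = extract_features(_epoch(data), algorithm, aux=_aux()).values
    scaled = extract_features(_epoch(3.0 * data), algorithm, aux=_aux()).values
    np.testing.assert_allclose(scaled, 3.0**exponent * base, rtol=1e-9)


def test_features_are_nonnegative(rng):
    epoch = _epoch(rng.normal(0, 2, (5, 500)))
    for alg in "ABCDE":
        assert (extract_features(epoch, alg, aux=_aux()).values >= 0).all()


class TestOptimalFrequencies:
    def _epochs(self, rng, attenuate_10hz):
        epochs = []
        for _ in range(8):
            sig = np.zeros((5, 500))
            for ch in range(5):
                a10 = 0.3 if attenuate_10hz else 1.0
                sig[ch] = 5.0 * a10 * np.sin(
                    2 * np.pi * 10.0 * T + rng.uniform(0, 2 * np.pi)
                ) + 0.3 * rng.normal(0, 1, 500)
            epochs.append(_epoch(sig))
        return epochs

    def test_finds_attenuated_frequency(self, rng):
        rest = self._epochs(rng, attenuate_10hz=False)
        start = self._epochs(rng, attenuate_10hz=True)
        opt = fit_optimal_frequencies(rest, start)
        # the 1 s boxcar leaks a pure tone into the two adjacent 0.5 Hz bins
        assert np.all(np.abs(opt.frequencies - 10.0) <= 0.5)

    def test_identical_classes_tie_to_lowest_grid_frequency(self, rng):
        epochs = self._epochs(rng, attenuate_10hz=False)
        opt = fit_optimal_frequencies(epochs, epochs)
        np.testing.assert_array_equal(opt.frequencies, 8.0)

    def test_candidate_grid(self):
        assert len(OPTIMAL_FREQ_GRID) == 41
        np.testing.assert_allclose(OPTIMAL_FREQ_GRID, np.arange(8.0, 28.5, 0.5))

    def test_mismatched_channels_rejected(self, rng):
        rest = self._epochs(rng, False)
        start = [
            _epoch(e.data, names=["P7", "P4", "PZ", "O1", "O2"]) for e in self._epochs(rng, True)
        ]
        with pytest.raises(ValidationError):
            fit_optimal_frequencies(rest, start)

    def test_out_of_grid_frequency_rejected(self):
        with pytest.raises(ValidationError):
            OptimalFrequencies(["C3"], [40.0])


def test_algorithm_d_band_mean_matches_independent_implementation(rng):
    data = rng.normal(0, 1, (5, 500))
    fstar = 14.5
    fv = extract_features(_epoch(data), "D", aux=_aux(fstar))
    # independent: mean-detrended, zero-padded raw-DFT periodogram,
    # mean of 0.5 Hz bins in [f*-1, f*+1]
    data = data - data.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(data, n=1000, axis=-1)) ** 2 / (FS * 500)
    spec[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(1000, 1 / FS)
    band = (freqs >= fstar - 1 - 1e-9) & (freqs <= fstar + 1 + 1e-9)
    np.testing.assert_allclose(fv.values, spec[:, band].mean(axis=1), rtol=1e-9)


def test_algorithm_d_requires_fitted_frequencies(rng):
    with pytest.raises(ValidationError):
        extract_features(_epoch(rng.normal(0, 1, (5, 500))), "D")


def test_unknown_algorithm_rejected(rng):
    with pytest.raises(ValidationError):
        extract_features(_epoch(rng.normal(0, 1, (5, 500))), "Z")
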