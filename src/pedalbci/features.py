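"""Feature-extraction algorithms A-E on preprocessed, channel-selected epochs.

All five algorithms summarize the epoch's spectrum per electrode:

* **A** — mean band power (PSD) over 18-28 Hz; 1 feature/electrode.
* **B** — Euclidean norm of the 0-50 Hz magnitude spectrum at 1 Hz
  resolution (51 bins); 1 feature/electrode.
* **C** — mean PSD over 1-4 Hz, 8-12 Hz and 13-28 Hz; 3 features/electrode.
* **D** — mean PSD over a per-electrode *optimal frequency* ± 1 Hz, where
  the optimal frequency maximizes the normalized class-mean spectral
  difference between rest and start on an 8-28 Hz, 0.5 Hz grid; 1
  feature/electrode (the fitted frequencies are part of the model).
* **E** — sums of 1 Hz magnitude bins over mu (8-12 Hz), low beta
  ((12, 24] Hz) and high beta ((24, 30] Hz); 3 features/electrode.

The PSD estimator is the raw periodogram of the 1 s epoch (native 1 Hz
resolution); algorithm D's 0.5 Hz grid is obtained by zero-padding to 2 s.
Band edges are inclusive except where two of algorithm E's bands share an
edge, in which case the shared frequency belongs to the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .windows import Epoch

ALGORITHMS = ("A", "B", "C", "D", "E")

#: Features per electrode for each algorithm.
FEATURES_PER_CHANNEL = {"A": 1, "B": 1, "C": 3, "D": 1, "E": 3}

#: Algorithm D's candidate grid: 8-28 Hz at 0.5 Hz resolution (41 points).
OPTIMAL_FREQ_GRID = np.arange(16, 57) * 0.5


@dataclass
class SpectralEstimate:
    """Uniform-grid spectral estimate for one epoch (channels x frequencies)."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float


@dataclass
class OptimalFrequencies:
    """Per-channel optimal frequency (Hz) fitted for algorithm D."""

    channel_names: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.channel_names) != len(self.frequencies):
            raise ValidationError("one optimal frequency per channel required")
        lo, hi = OPTIMAL_FREQ_GRID[0], OPTIMAL_FREQ_GRID[-1]
        if np.any(self.frequencies < lo) or np.any(self.frequencies > hi):
            raise ValidationError(f"optimal frequencies must lie in [{lo}, {hi}] Hz")

    def subset(self, channels: list[str]) -> "OptimalFrequencies":
        index = {c: i for i, c in enumerate(self.channel_names)}
        missing = [c for c in channels if c not in index]
        if missing:
            raise ValidationError(f"no optimal frequency fitted for channels {missing}")
        return OptimalFrequencies(
            list(channels), self.frequencies[[index[c] for c in channels]]
        )


@dataclass
class FeatureVector:
    algorithm: str
    values: np.ndarray
    epoch_time: float = float("nan")
    config_id: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def periodogram_psd(data: np.ndarray, fs: float, resolution: float = 1.0) -> SpectralEstimate:
    """Raw periodogram PSD of ``data`` (time on the last axis).

    Zero-pads when the requested resolution is finer than the epoch's
    native 1/T resolution.
    """
    nfft = max(data.shape[-1], int(round(fs / resolution)))
    freqs, psd = sps.periodogram(data, fs=fs, nfft=nfft, axis=-1)
    return SpectralEstimate(freqs, psd, freqs[1] - freqs[0])


def amplitude_spectrum(data: np.ndarray, fs: float, resolution: float = 1.0) -> SpectralEstimate:
    """One-sided magnitude spectrum on a uniform grid (time on last axis)."""
    n = data.shape[-1]
    nfft = max(n, int(round(fs / resolution)))
    spec = np.abs(np.fft.rfft(data, n=nfft, axis=-1)) / n
    spec = spec * 2.0
    spec[..., 0] /= 2.0
    if nfft % 2 == 0:
        spec[..., -1] /= 2.0
    freqs = np.arange(spec.shape[-1]) * fs / nfft
    return SpectralEstimate(freqs, spec, fs / nfft)


def _band_idx(lo: float, hi: float, resolution: float) -> slice:
    """Index slice of the inclusive band [lo, hi] on a uniform grid."""
    return slice(int(round(lo / resolution)), int(round(hi / resolution)) + 1)


def fit_optimal_frequencies(
    rest_epochs: list[Epoch] | np.ndarray,
    start_epochs: list[Epoch] | np.ndarray,
    channel_names: list[str] | None = None,
    fs: float = 500.0,
) -> OptimalFrequencies:
    """Fit algorithm D's per-channel optimal frequencies from labeled epochs.

    For every channel the class-mean PSD over 8-28 Hz (0.5 Hz resolution)
    of each class is normalized to unit sum over the band, and the grid
    frequency with the largest absolute difference between the normalized
    class spectra is selected.  Ties resolve to the lowest frequency.
    """
    rest, names_r = _stack(rest_epochs, channel_names, fs)
    start, names_s = _stack(start_epochs, channel_names, fs)
    if names_r != names_s:
        raise ValidationError("rest and start epochs have mismatched channel sets")
    if rest.shape[0] == 0 or start.shape[0] == 0:
        raise ValidationError("both classes must be non-empty")
    fs = fs if not isinstance(rest_epochs, list) else rest_epochs[0].sampling_rate

    band = _band_idx(8.0, 28.0, 0.5)
    diff = _normalized_band_mean(rest, fs, band) - _normalized_band_mean(start, fs, band)
    best = np.argmax(np.abs(diff), axis=-1)
    return OptimalFrequencies(names_r, OPTIMAL_FREQ_GRID[best])


def _normalized_band_mean(data: np.ndarray, fs: float, band: slice) -> np.ndarray:
    psd = periodogram_psd(data, fs, resolution=0.5).power[..., band]
    mean = psd.mean(axis=0)
    total = mean.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, mean / np.where(total > 0, total, 1.0), 0.0)
    return out


def _stack(
    epochs: list[Epoch] | np.ndarray, channel_names: list[str] | None, fs: float
) -> tuple[np.ndarray, list[str]]:
    if isinstance(epochs, np.ndarray):
        if channel_names is None:
            raise ValidationError("channel_names required with array input")
        return epochs, list(channel_names)
    if not epochs:
        return np.empty((0, 0, 0)), list(channel_names or [])
    names = list(epochs[0].channel_names)
    for e in epochs:
        if list(e.channel_names) != names:
            raise ValidationError("epochs have mismatched channel sets")
    return np.stack([e.data for e in epochs]), names


def batch_features(
    data: np.ndarray,
    fs: float,
    algorithm: str,
    optimal: OptimalFrequencies | None = None,
) -> np.ndarray:
    """Feature matrix for a stack of epochs (epochs x channels x samples).

    Returns an (epochs, n_channels * k) array, channel-major ordering.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(f"unknown feature algorithm {algorithm!r}")
    if algorithm == "A":
        psd = periodogram_psd(data, fs, 1.0)
        feats = psd.power[..., _band_idx(18, 28, psd.resolution)].mean(axis=-1, keepdims=True)
    elif algorithm == "B":
        amp = amplitude_spectrum(data, fs, 1.0)
        band = amp.power[..., _band_idx(0, 50, amp.resolution)]
        feats = np.linalg.norm(band, axis=-1, keepdims=True)
    elif algorithm == "C":
        psd = periodogram_psd(data, fs, 1.0)
        r = psd.resolution
        feats = np.stack(
            [
                psd.power[..., _band_idx(1, 4, r)].mean(axis=-1),
                psd.power[..., _band_idx(8, 12, r)].mean(axis=-1),
                psd.power[..., _band_idx(13, 28, r)].mean(axis=-1),
            ],
            axis=-1,
        )
    elif algorithm == "D":
        if optimal is None:
            raise ValidationError("algorithm D requires fitted optimal frequencies")
        if len(optimal.frequencies) != data.shape[-2]:
            raise ValidationError("optimal frequencies do not match the epoch's channels")
        psd = periodogram_psd(data, fs, 0.5)
        r = psd.resolution
        half = int(round(1.0 / r))
        centers = np.round(optimal.frequencies / r).astype(int)
        offsets = np.arange(-half, half + 1)
        idx = centers[:, None] + offsets[None, :]  # (channels, band bins)
        feats = np.take_along_axis(
            psd.power, np.broadcast_to(idx, data.shape[:-1] + (idx.shape[1],)), axis=-1
        ).mean(axis=-1, keepdims=True)
    else:  # E
        amp = amplitude_spectrum(data, fs, 1.0)
        r = amp.resolution
        # shared edges 12 and 24 Hz belong to the lower band
        feats = np.stack(
            [
                amp.power[..., _band_idx(8, 12, r)].sum(axis=-1),
                amp.power[..., _band_idx(13, 24, r)].sum(axis=-1),
                amp.power[..., _band_idx(25, 30, r)].sum(axis=-1),
            ],
            axis=-1,
        )
    return feats.reshape(data.shape[:-2] + (-1,))


def extract_features(
    epoch: Epoch, algorithm: str, aux: OptimalFrequencies | None = None
) -> FeatureVector:
    """Feature vector of one epoch under the given algorithm.

    Algorithm D requires ``aux``; its frequencies are aligned to the
    epoch's channel order (a subset fit is taken when needed).
    """
    optimal = aux
    if algorithm == "D" and aux is not None and aux.channel_names != epoch.channel_names:
        optimal = aux.subset(epoch.channel_names)
    values = batch_features(epoch.data[None], epoch.sampling_rate, algorithm, optimal)[0]
    return FeatureVector(algorithm=algorithm, values=values, epoch_time=epoch.start_time)
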