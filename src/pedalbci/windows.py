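"""Class windows around movement onset and overlapping 1 s epoch slicing.

The start class window spans 2 s before the onset (2 s window type) or
2 s before to 2 s after (4 s type); the rest window has the same duration
and precedes it with a 0.5 s gap.  Windows are sliced into 1 s epochs
stepped by 200 ms, giving 6 decisions per 2 s window and 16 per 4 s
window.  All intervals are half-open ``[t0, t1)``; epoch start times sit
on the sample grid, fractional boundaries rounding inward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_model import EEGRecording
from .errors import ValidationError

WindowType = Literal["2s", "4s"]

WINDOW_LENGTHS_S: dict[str, float] = {"2s": 2.0, "4s": 4.0}

#: Gap between the rest and start class windows.
CLASS_GAP_S = 0.5


@dataclass(frozen=True)
class ClassWindow:
    """A labeled half-open interval tied to one pedaling cycle."""

    label: Literal["rest", "start"]
    t0: float
    t1: float
    cycle_index: int = -1

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def contains(self, t: float) -> bool:
        return self.t0 <= t < self.t1


@dataclass(frozen=True)
class EpochingParams:
    epoch_length: float = 1.0
    shift: float = 0.2
    window_type: WindowType = "4s"

    def __post_init__(self) -> None:
        if self.shift <= 0:
            raise ValidationError("epoch shift must be positive")
        if self.epoch_length > WINDOW_LENGTHS_S[self.window_type]:
            raise ValidationError("epoch length exceeds the class window length")


@dataclass
class Epoch:
    """A channels x samples slice of EEG; the atomic classification unit."""

    start_time: float
    data: np.ndarray
    channel_names: list[str]
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("epoch data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError("epoch channel names do not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def build_class_windows(
    onset_time: float,
    window_type: WindowType,
    cycle_index: int = -1,
    cycle_start: float | None = None,
) -> tuple[ClassWindow, ClassWindow]:
    """Rest and start class windows around one movement onset.

    4 s type: start = [onset-2, onset+2), rest = [onset-6.5, onset-2.5).
    2 s type: start = [onset-2, onset),   rest = [onset-4.5, onset-2.5).
    """
    if window_type not in WINDOW_LENGTHS_S:
        raise ValidationError(f"unknown window type {window_type!r}")
    length = WINDOW_LENGTHS_S[window_type]
    start_t0 = onset_time - 2.0
    start_t1 = start_t0 + length
    rest_t1 = start_t0 - CLASS_GAP_S
    rest_t0 = rest_t1 - length
    if cycle_start is not None and rest_t0 < cycle_start - 1e-9:
        raise ValidationError(
            f"insufficient rest: rest window starts at {rest_t0:.2f}s, "
            f"before cycle start {cycle_start:.2f}s"
        )
    return (
        ClassWindow("rest", rest_t0, rest_t1, cycle_index),
        ClassWindow("start", start_t0, start_t1, cycle_index),
    )


def epoch_start_indices(
    t0: float, t1: float, sampling_rate: float, epoch_length: float, shift: float
) -> np.ndarray:
    """Sample indices of every epoch start fully inside ``[t0, t1)``."""
    n_epoch = int(round(epoch_length * sampling_rate))
    n_shift = int(round(shift * sampling_rate))
    i0 = int(np.ceil(t0 * sampling_rate - 1e-9))
    i1 = int(np.floor(t1 * sampling_rate + 1e-9))
    n_avail = i1 - i0
    if n_avail < n_epoch:
        return np.empty(0, dtype=int)
    n_epochs = (n_avail - n_epoch) // n_shift + 1
    return i0 + n_shift * np.arange(n_epochs)


def slice_epochs(
    signal: EEGRecording,
    interval: tuple[float, float] | ClassWindow,
    params: EpochingParams,
) -> list[Epoch]:
    """Slice ``interval`` of the recording into overlapping epochs.

    Epoch count is ``floor((L - epoch_length)/shift) + 1`` for an interval
    of length L >= epoch_length, else the list is empty.  No epoch crosses
    the interval's right edge.
    """
    if isinstance(interval, ClassWindow):
        t0, t1 = interval.t0, interval.t1
    else:
        t0, t1 = interval
    fs = signal.sampling_rate
    t1 = min(t1, signal.start_time + signal.duration)
    starts = epoch_start_indices(
        t0 - signal.start_time, t1 - signal.start_time, fs, params.epoch_length, params.shift
    )
    n_epoch = int(round(params.epoch_length * fs))
    return [
        Epoch(
            start_time=signal.start_time + i / fs,
            data=signal.samples[:, i : i + n_epoch],
            channel_names=list(signal.channel_names),
            sampling_rate=fs,
        )
        for i in starts
    ]
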