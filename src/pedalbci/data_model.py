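"""Session data model: EEG block, IMU block, event table and protocol metadata.

All times are seconds from session start; intervals are half-open
``[start, end)``.  EEG amplitudes are microvolts, IMU angular velocities
degrees per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Minimum cue-to-movement wait; cycles violating it are discarded.
MIN_WAIT_S = 3.0

IMU_TRACE_NAMES = ("left_ankle", "left_tibialis", "right_ankle", "right_tibialis")

EVENT_COLUMNS = ["trial", "cycle", "cue_time_s", "real_start_time_s", "discarded", "reason"]


@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is a channels x time matrix in microvolts.

    Channel names follow the international 10-10 system; the default montage
    has 32 channels sampled at 500 Hz.
    """

    channel_names: list[str]
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("EEG sampling_rate must be positive")
        if self.samples.ndim != 2:
            raise ValidationError("EEG samples must be a 2-D channels x time matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names but "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("EEG channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class IMURecording:
    """Gyroscope-X angular velocity, two sensors per leg, sampled at 20 Hz.

    ``traces`` maps the four trace names (``left_ankle``, ``left_tibialis``,
    ``right_ankle``, ``right_tibialis``) to equal-length 1-D arrays in deg/s.
    """

    traces: dict[str, np.ndarray]
    sampling_rate: float = 20.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("IMU sampling_rate must be positive")
        missing = set(IMU_TRACE_NAMES) - set(self.traces)
        if missing:
            raise ValidationError(f"IMU recording missing traces: {sorted(missing)}")
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) != 1:
            raise ValidationError("all IMU traces must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def leg_average(self, leg: str) -> np.ndarray:
        """Mean of the two sensor traces of one leg ("left" or "right")."""
        return 0.5 * (self.traces[f"{leg}_ankle"] + self.traces[f"{leg}_tibialis"])


@dataclass
class EventTable:
    """Per-cycle events: cue time, detected real start, discarded flag.

    ``real_start_time_s`` is NaN until onset detection has run (or the
    generator recorded the true onset).  Non-discarded cycles satisfy
    ``real_start_time_s >= cue_time_s + 3``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        if "reason" not in df.columns:
            df["reason"] = ""
        df["reason"] = df["reason"].fillna("")
        df = df[EVENT_COLUMNS]
        df["trial"] = df["trial"].astype(int)
        df["cycle"] = df["cycle"].astype(int)
        df["discarded"] = df["discarded"].astype(bool)
        self.table = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.table
        for trial, grp in df.groupby("trial"):
            if not grp["cue_time_s"].is_monotonic_increasing:
                raise ValidationError(f"cue times not nondecreasing within trial {trial}")
        ok = ~df["discarded"] & df["real_start_time_s"].notna()
        bad = df.loc[ok, "real_start_time_s"] < df.loc[ok, "cue_time_s"] + MIN_WAIT_S - 1e-9
        if bad.any():
            idx = bad.idxmax()
            raise ValidationError(
                "non-discarded cycle with real start earlier than cue + "
                f"{MIN_WAIT_S} s (row {idx})"
            )

    def __len__(self) -> int:
        return len(self.table)

    def active(self) -> pd.DataFrame:
        """Rows for non-discarded cycles with a detected onset."""
        df = self.table
        return df[~df["discarded"] & df["real_start_time_s"].notna()]

    def copy(self) -> "EventTable":
        return EventTable(self.table.copy())


@dataclass
class ProtocolParams:
    """Experimental protocol: trials, cycles and nominal segment durations."""

    n_trials: int = 16
    cycles_per_trial: int = 5
    rest_s: float = 10.0
    pedal_s: float = 5.0

    def validate(self) -> None:
        if self.n_trials < 1 or self.cycles_per_trial < 1:
            raise ValidationError("protocol needs at least one trial and one cycle")
        if self.rest_s <= 0 or self.pedal_s <= 0:
            raise ValidationError("rest and pedal durations must be positive")


@dataclass
class Session:
    """One subject's recording: EEG, IMU, events, protocol metadata."""

    subject_id: str
    eeg: EEGRecording
    imu: IMURecording
    events: EventTable
    protocol: ProtocolParams = field(default_factory=ProtocolParams)

    def validate(self) -> None:
        self.eeg.validate()
        self.imu.validate()
        self.events.validate()
        self.protocol.validate()

    def cycle_intervals(self) -> list[tuple[float, float]]:
        """Half-open [start, end) interval of each cycle, in event-table order.

        A cycle starts ``rest_s`` before its cue; the last cycle ends at the
        end of the EEG recording.
        """
        cues = self.events.table["cue_time_s"].to_numpy()
        starts = np.maximum(cues - self.protocol.rest_s, 0.0)
        ends = np.append(starts[1:], self.eeg.start_time + self.eeg.duration)
        return list(zip(starts.tolist(), ends.tolist()))
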