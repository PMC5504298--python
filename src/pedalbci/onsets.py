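"""Movement-onset ("real start") detection from IMU angular velocities.

The two sensor traces of each leg are averaged; the real start of a cycle
is the earliest IMU sample at or after the cue where the absolute averaged
angular velocity of *both* legs exceeds the threshold.  Cycles whose
detected start comes less than 3 s after the cue, or where no crossing
occurs before the next cycle, are flagged discarded.  Resolution is the
20 Hz IMU grid; no interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MIN_WAIT_S, EventTable, IMURecording
from .errors import ValidationError


@dataclass(frozen=True)
class OnsetParams:
    """Detection threshold in deg/s applied to the rectified leg averages."""

    threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("onset threshold must be positive")


def detect_real_starts(
    imu: IMURecording, events: EventTable, params: OnsetParams = OnsetParams()
) -> EventTable:
    """Fill ``real_start_time_s`` for every cycle; flag late/absent onsets.

    The search window of a cycle is [cue, next cue) (or the end of the IMU
    recording for the last cycle).  The input table is not modified.
    """
    left = np.abs(imu.leg_average("left"))
    right = np.abs(imu.leg_average("right"))
    both = (left > params.threshold) & (right > params.threshold)
    times = imu.times()

    df = events.table.copy()
    cues = df["cue_time_s"].to_numpy()
    ends = np.append(cues[1:], times[-1] + 1.0 / imu.sampling_rate if len(times) else 0.0)

    for i, (cue, end) in enumerate(zip(cues, ends)):
        lo = int(np.ceil((cue - imu.start_time) * imu.sampling_rate - 1e-9))
        hi = int(np.ceil((end - imu.start_time) * imu.sampling_rate - 1e-9))
        lo, hi = max(lo, 0), min(hi, len(times))
        window = both[lo:hi]
        hits = np.flatnonzero(window)
        if hits.size == 0:
            df.loc[df.index[i], ["real_start_time_s", "discarded", "reason"]] = (
                np.nan,
                True,
                "no onset",
            )
            continue
        onset = times[lo + hits[0]]
        df.loc[df.index[i], "real_start_time_s"] = onset
        if onset - cue < MIN_WAIT_S:
            df.loc[df.index[i], ["discarded", "reason"]] = (True, "early start")
    return EventTable(df)
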