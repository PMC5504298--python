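"""Read/write the session directory format; optional EDF import for EEG.

A session directory holds four plain-text files:

* ``meta.json`` — subject id, sampling rates, amplitude unit, protocol.
* ``eeg.tsv`` — ``time_s`` column followed by one column per channel (µV).
* ``imu.tsv`` — ``time_s``, ``left_ankle``, ``left_tibialis``,
  ``right_ankle``, ``right_tibialis`` (deg/s).
* ``events.tsv`` — ``trial``, ``cycle``, ``cue_time_s``,
  ``real_start_time_s``, ``discarded``, ``reason``.

Values are written with enough digits to round-trip float64 to better than
1e-9 relative precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    EVENT_COLUMNS,
    IMU_TRACE_NAMES,
    EEGRecording,
    EventTable,
    IMURecording,
    ProtocolParams,
    Session,
)
from .errors import ValidationError

_FLOAT_FMT = "%.12g"


def write_session(session: Session, path: str | Path) -> None:
    """Write a validated session to ``path`` (created if absent)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "subject_id": session.subject_id,
        "eeg_sampling_rate_hz": session.eeg.sampling_rate,
        "eeg_unit": "uV",
        "eeg_start_time_s": session.eeg.start_time,
        "imu_sampling_rate_hz": session.imu.sampling_rate,
        "imu_unit": "deg/s",
        "imu_start_time_s": session.imu.start_time,
        "protocol": {
            "n_trials": session.protocol.n_trials,
            "cycles_per_trial": session.protocol.cycles_per_trial,
            "rest_s": session.protocol.rest_s,
            "pedal_s": session.protocol.pedal_s,
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")

    eeg_df = pd.DataFrame(session.eeg.samples.T, columns=session.eeg.channel_names)
    eeg_df.insert(0, "time_s", session.eeg.times())
    eeg_df.to_csv(path / "eeg.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    imu_df = pd.DataFrame({name: session.imu.traces[name] for name in IMU_TRACE_NAMES})
    imu_df.insert(0, "time_s", session.imu.times())
    imu_df.to_csv(path / "imu.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    session.events.table.to_csv(
        path / "events.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`ValidationError` on missing files, metadata/sample
    mismatches or invariant violations.
    """
    path = Path(path)
    for fname in ("meta.json", "eeg.tsv", "imu.tsv", "events.tsv"):
        if not (path / fname).exists():
            raise ValidationError(f"session directory missing {fname}: {path}")
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed meta.json: {exc}") from exc

    eeg_df = pd.read_csv(path / "eeg.tsv", sep="\t")
    if eeg_df.columns[0] != "time_s":
        raise ValidationError("eeg.tsv must start with a time_s column")
    channels = list(eeg_df.columns[1:])
    times = eeg_df["time_s"].to_numpy()
    fs = float(meta["eeg_sampling_rate_hz"])
    if len(times) > 1:
        dt = np.median(np.diff(times))
        if abs(dt * fs - 1.0) > 1e-6:
            raise ValidationError(
                f"eeg.tsv sample spacing {dt:.6g}s inconsistent with metadata rate {fs}Hz"
            )
    eeg = EEGRecording(
        channel_names=channels,
        sampling_rate=fs,
        samples=eeg_df[channels].to_numpy().T,
        start_time=float(meta.get("eeg_start_time_s", times[0] if len(times) else 0.0)),
    )

    imu_df = pd.read_csv(path / "imu.tsv", sep="\t")
    missing = set(IMU_TRACE_NAMES) - set(imu_df.columns)
    if missing:
        raise ValidationError(f"imu.tsv missing columns: {sorted(missing)}")
    imu = IMURecording(
        traces={name: imu_df[name].to_numpy() for name in IMU_TRACE_NAMES},
        sampling_rate=float(meta["imu_sampling_rate_hz"]),
        start_time=float(meta.get("imu_start_time_s", 0.0)),
    )

    ev_df = pd.read_csv(path / "events.tsv", sep="\t")
    if "reason" not in ev_df.columns:
        ev_df["reason"] = ""
    ev_df["reason"] = ev_df["reason"].fillna("").astype(str)
    missing = set(EVENT_COLUMNS) - set(ev_df.columns)
    if missing:
        raise ValidationError(f"events.tsv missing columns: {sorted(missing)}")
    events = EventTable(ev_df)

    proto = meta.get("protocol", {})
    session = Session(
        subject_id=str(meta["subject_id"]),
        eeg=eeg,
        imu=imu,
        events=events,
        protocol=ProtocolParams(
            n_trials=int(proto.get("n_trials", 16)),
            cycles_per_trial=int(proto.get("cycles_per_trial", 5)),
            rest_s=float(proto.get("rest_s", 10.0)),
            pedal_s=float(proto.get("pedal_s", 5.0)),
        ),
    )
    session.validate()
    return session


def read_eeg_edf(path: str | Path) -> EEGRecording:
    """Import an EDF file's channels as an :class:`EEGRecording` (in µV).

    Convenience import; requires ``mne``.  Channels whose EDF physical unit
    is volts are rescaled to microvolts (mne loads EEG data in volts).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # volts for EEG channel types
    return EEGRecording(
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        samples=data * 1e6,
        start_time=0.0,
    )
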