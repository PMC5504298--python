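"""Synthetic session generator with protocol timing and ERD/ERS structure.

The generator emulates the acquisition protocol (16 trials x 5 pedaling
cycles; ~10 s rest, cue, a volitional wait of at least 3 s, ~5 s pedaling)
and the statistical signature the pipeline assumes: per-channel narrowband
mu/beta oscillators riding on 1/f background noise, with the affected
band's amplitude envelope attenuated by ``1 - erd_depth`` from 2 s before
movement onset (ERD) and rebounding by ``1 + ers_gain`` starting about 2 s
after onset (ERS), heterogeneous across subjects in spatial location and
band.  IMU traces are near-zero at rest and oscillate at pedaling
amplitude during the pedaling segments of both legs.

A fixed seed yields a byte-identical session.  This is a statistical
emulation, not a biophysical one: no volume conduction, eye blinks, EMG
artifacts or slow cortical potentials are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    EEGRecording,
    EventTable,
    IMURecording,
    ProtocolParams,
    Session,
)
from .errors import ValidationError
from .montage import MONTAGE_32

#: Duration of window + gap that must fit between cycle start and onset - 2 s.
_MIN_PRE_ONSET_S = 6.5


@dataclass(frozen=True)
class SubjectProfile:
    """Where and how strongly a synthetic subject expresses ERD/ERS.

    ``affected_band`` is a (low, high) Hz range within mu/beta whose center
    becomes the frequency of the modulated oscillator on the affected
    channels.  ``erd_depth`` is the fractional amplitude attenuation in
    [0, 1]; ``ers_gain`` the fractional rebound.  ERD spans
    ``[onset - erd_onset_lead, onset + ers_onset_delay)`` and the ERS
    rebound ``[onset + ers_onset_delay, onset + ers_onset_delay +
    ers_duration)``.
    """

    affected_channels: tuple[str, ...] = ("C3", "C1")
    affected_band: tuple[float, float] = (9.0, 11.0)
    erd_depth: float = 0.5
    ers_gain: float = 0.5
    erd_onset_lead: float = 2.0
    ers_onset_delay: float = 2.0
    ers_duration: float = 2.0
    noise_amp: float = 2.0
    mu_amp: float = 6.0
    beta_amp: float = 4.0
    envelope_std: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValidationError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ValidationError("ers_gain must be nonnegative")
        unknown = [c for c in self.affected_channels if c not in MONTAGE_32]
        if unknown:
            raise ValidationError(f"affected channels not in montage: {unknown}")


@dataclass(frozen=True)
class SynthParams:
    """Everything needed to generate one session deterministically."""

    profile: SubjectProfile = field(default_factory=SubjectProfile)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    line_amp: float = 1.0
    imu_noise: float = 1.0
    pedal_amp: float = 50.0
    cadence_hz: float = 1.0
    eeg_rate: float = 500.0
    imu_rate: float = 20.0
    seed: int = 0
    subject_id: str = "S1"


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, normalized to ``rms``."""
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(nf)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(nf) + 1j * rng.standard_normal(nf)) * shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _smooth_envelope(rng: np.random.Generator, n: int, fs: float, std: float) -> np.ndarray:
    """Slowly varying positive amplitude envelope around 1 (~0.5 s timescale)."""
    coarse_rate = 2.0
    n_coarse = max(int(np.ceil(n / fs * coarse_rate)) + 2, 4)
    coarse = rng.standard_normal(n_coarse)
    t = np.arange(n) / fs
    env = 1.0 + std * np.interp(t * coarse_rate, np.arange(n_coarse), coarse)
    return np.clip(env, 0.05, None)


def generate_session(params: SynthParams) -> Session:
    """Generate a full synthetic session from ``params`` (deterministic)."""
    proto = params.protocol
    proto.validate()
    if proto.rest_s < _MIN_PRE_ONSET_S - 2.0 - 1.0:
        raise ValidationError(
            f"rest period {proto.rest_s}s too short for the rest class window "
            "(window + gap must fit before onset - 2 s)"
        )
    prof = params.profile
    ss = np.random.SeedSequence(params.seed)
    rng_timing, rng_noise, rng_rhythm, rng_imu = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # protocol timeline
    rows = []
    t = 0.0
    for trial in range(1, proto.n_trials + 1):
        for cycle in range(1, proto.cycles_per_trial + 1):
            cue = t + proto.rest_s
            wait = rng_timing.uniform(3.0, 4.5)
            onset = cue + wait
            pedal = rng_timing.uniform(proto.pedal_s - 0.5, proto.pedal_s + 0.5)
            rows.append(
                {
                    "trial": trial,
                    "cycle": cycle,
                    "cue_time_s": cue,
                    "real_start_time_s": onset,
                    "discarded": False,
                    "reason": "",
                }
            )
            t = onset + pedal
    duration = t + 1.0
    events = EventTable(pd.DataFrame(rows))
    onsets = events.table["real_start_time_s"].to_numpy()
    cycle_ends = np.append(
        events.table["cue_time_s"].to_numpy()[1:] - proto.rest_s, duration
    )

    # EEG
    fs = params.eeg_rate
    n = int(round(duration * fs))
    times = np.arange(n) / fs

    erd_gain = np.ones(n)
    for onset in onsets:
        a = int(round((onset - prof.erd_onset_lead) * fs))
        b = int(round((onset + prof.ers_onset_delay) * fs))
        c = int(round((onset + prof.ers_onset_delay + prof.ers_duration) * fs))
        erd_gain[max(a, 0) : min(b, n)] = 1.0 - prof.erd_depth
        erd_gain[max(b, 0) : min(c, n)] = 1.0 + prof.ers_gain

    f_affected = 0.5 * (prof.affected_band[0] + prof.affected_band[1])
    affected_is_mu = f_affected <= 15.0
    line_phase = rng_rhythm.uniform(0, 2 * np.pi)
    line = params.line_amp * np.sin(2 * np.pi * 50.0 * times + line_phase)

    eeg = np.empty((len(MONTAGE_32), n), dtype=np.float32)
    for i, ch in enumerate(MONTAGE_32):
        x = _one_over_f_noise(rng_noise, n, fs, prof.noise_amp)
        affected = ch in prof.affected_channels
        for which, base_freq, amp in (("mu", 10.0, prof.mu_amp), ("beta", 20.0, prof.beta_amp)):
            freq = base_freq
            modulated = False
            if affected and ((which == "mu") == affected_is_mu):
                freq, modulated = f_affected, True
            phase = rng_rhythm.uniform(0, 2 * np.pi)
            env = _smooth_envelope(rng_rhythm, n, fs, prof.envelope_std)
            if modulated:
                env = env * erd_gain
            x = x + amp * env * np.sin(2 * np.pi * freq * times + phase)
        eeg[i] = x + line

    eeg_rec = EEGRecording(
        channel_names=list(MONTAGE_32), sampling_rate=fs, samples=eeg, start_time=0.0
    )

    # IMU: noise at rest, antiphase pedaling oscillation between legs
    n20 = int(round(duration * params.imu_rate))
    t20 = np.arange(n20) / params.imu_rate
    pedal_wave = np.zeros(n20)
    for onset, end in zip(onsets, cycle_ends):
        mask = (t20 >= onset) & (t20 < end)
        pedal_wave[mask] = params.pedal_amp * np.sin(
            2 * np.pi * params.cadence_hz * (t20[mask] - onset)
        )
    traces = {}
    for name, sign in (
        ("left_ankle", 1.0),
        ("left_tibialis", 1.0),
        ("right_ankle", -1.0),
        ("right_tibialis", -1.0),
    ):
        traces[name] = sign * pedal_wave + params.imu_noise * rng_imu.standard_normal(n20)
    imu_rec = IMURecording(traces=traces, sampling_rate=params.imu_rate, start_time=0.0)

    return Session(
        subject_id=params.subject_id,
        eeg=eeg_rec,
        imu=imu_rec,
        events=events,
        protocol=proto,
    )


#: Archetype (channels, band) pairs cycled through by :func:`generate_cohort`;
#: lateralized and midline sites over motor/premotor/central-parietal areas.
COHORT_ARCHETYPES: list[tuple[tuple[str, ...], tuple[float, float]]] = [
    (("C3", "C1"), (9.0, 11.0)),
    (("C2", "C4"), (19.0, 21.0)),
    (("CZ", "FC1", "FC2"), (10.0, 12.0)),
    (("CP1", "CP5"), (9.0, 11.0)),
    (("CP2", "CP6"), (19.0, 21.0)),
]


def generate_cohort(
    n_subjects: int,
    seed: int = 0,
    erd_depth: float = 0.7,
    ers_gain: float = 0.6,
    protocol: ProtocolParams | None = None,
) -> list[SynthParams]:
    """Parameter sets for ``n_subjects`` heterogeneous synthetic subjects.

    Profiles cycle through lateralized/midline archetypes differing in the
    affected channel subset and band, so that different electrode
    configurations are optimal for different subjects.
    """
    if n_subjects < 1:
        raise ValidationError("cohort needs at least one subject")
    seeds = (np.random.SeedSequence(seed).generate_state(n_subjects) >> 1).tolist()
    cohort = []
    for k in range(n_subjects):
        channels, band = COHORT_ARCHETYPES[k % len(COHORT_ARCHETYPES)]
        profile = SubjectProfile(
            affected_channels=channels,
            affected_band=band,
            erd_depth=erd_depth,
            ers_gain=ers_gain,
        )
        cohort.append(
            SynthParams(
                profile=profile,
                protocol=protocol if protocol is not None else ProtocolParams(),
                seed=int(seeds[k]),
                subject_id=f"S{k + 1}",
            )
        )
    return cohort
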