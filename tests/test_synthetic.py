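"""Determinism, protocol structure and ERD/ERS statistics of the generator."""

import numpy as np
import pytest

from pedalbci.data_model import ProtocolParams
from pedalbci.errors import ValidationError
from pedalbci.synthetic import (
    SubjectProfile,
    SynthParams,
    generate_cohort,
    generate_session,
)

SMALL_PROTO = ProtocolParams(n_trials=2, cycles_per_trial=2, rest_s=7.0)


def test_fixed_seed_is_byte_identical():
    params = SynthParams(protocol=SMALL_PROTO, seed=99)
    a = generate_session(params)
    b = generate_session(params)
    assert np.array_equal(a.eeg.samples, b.eeg.samples)
    assert all(
        np.array_equal(a.imu.traces[k], b.imu.traces[k]) for k in a.imu.traces
    )
    assert a.events.table.equals(b.events.table)


def test_signal_lengths_match_protocol_duration(tiny_session):
    duration = tiny_session.eeg.duration
    assert abs(tiny_session.eeg.n_samples - duration * 500) <= 1
    assert abs(tiny_session.imu.n_samples - duration * 20) <= 1


def test_wait_always_at_least_three_seconds(tiny_session):
    df = tiny_session.events.table
    waits = df["real_start_time_s"] - df["cue_time_s"]
    assert (waits >= 3.0).all()
    assert (~df["discarded"]).all()


def test_rest_too_short_for_class_windows_rejected():
    with pytest.raises(ValidationError):
        generate_session(SynthParams(protocol=ProtocolParams(rest_s=3.0)))


def _band_power_ratio(session, channel, band, n_cycles=None):
    """Mean affected-band power in the pre-onset 2 s over mid-rest 2 s."""
    eeg = session.eeg
    i_ch = eeg.channel_names.index(channel)
    fs = eeg.sampling_rate
    lo, hi = band
    pre, rest = [], []
    rows = session.events.active()
    intervals = session.cycle_intervals()
    for idx, r in rows.iterrows():
        onset = r["real_start_time_s"]
        c0 = intervals[idx][0]
        for store, t0 in ((pre, onset - 2.0), (rest, c0 + 2.0)):
            i0 = int(round(t0 * fs))
            seg = eeg.samples[i_ch, i0 : i0 + int(2 * fs)].astype(float)
            spec = np.abs(np.fft.rfft(seg)) ** 2
            freqs = np.fft.rfftfreq(len(seg), 1 / fs)
            store.append(spec[(freqs >= lo - 1) & (freqs <= hi + 1)].sum())
        if n_cycles and len(pre) >= n_cycles:
            break
    return np.mean(pre) / np.mean(rest)


@pytest.fixture(scope="module")
def modulated_session():
    profile = SubjectProfile(
        affected_channels=("C3", "C1"), affected_band=(9.0, 11.0), erd_depth=0.5
    )
    params = SynthParams(
        profile=profile, protocol=ProtocolParams(n_trials=11, cycles_per_trial=5), seed=5
    )
    return generate_session(params)


def test_erd_depth_half_gives_quarter_power(modulated_session):
    # amplitude factor (1 - 0.5) -> band power factor 0.25, over >= 50 cycles
    ratio = _band_power_ratio(modulated_session, "C3", (9.0, 11.0))
    assert ratio == pytest.approx(0.25, abs=0.07)


def test_modulation_confined_to_profile_channels(modulated_session):
    # an unaffected channel passes the null-effect check
    ratio = _band_power_ratio(modulated_session, "C4", (9.0, 11.0))
    assert ratio == pytest.approx(1.0, abs=0.15)


def test_zero_depth_zero_gain_is_null_effect():
    profile = SubjectProfile(
        affected_channels=("C3",), affected_band=(9.0, 11.0), erd_depth=0.0, ers_gain=0.0
    )
    params = SynthParams(
        profile=profile, protocol=ProtocolParams(n_trials=11, cycles_per_trial=5), seed=6
    )
    session = generate_session(params)
    ratio = _band_power_ratio(session, "C3", (9.0, 11.0))
    assert ratio == pytest.approx(1.0, abs=0.15)


def test_imu_quiet_at_rest_active_while_pedaling(tiny_session):
    imu = tiny_session.imu
    t = imu.times()
    row = tiny_session.events.table.iloc[0]
    onset = row["real_start_time_s"]
    left = imu.leg_average("left")
    rest_mask = (t >= onset - 4) & (t < onset - 1)
    pedal_mask = (t >= onset + 0.2) & (t < onset + 2)
    assert np.abs(left[rest_mask]).max() < 10.0
    assert np.abs(left[pedal_mask]).max() > 30.0


def test_invalid_profiles_rejected():
    with pytest.raises(ValidationError):
        SubjectProfile(erd_depth=1.5)
    with pytest.raises(ValidationError):
        SubjectProfile(affected_channels=("NOT_A_CHANNEL",))


class TestCohort:
    def test_reproducible_and_distinct(self):
        a = generate_cohort(5, seed=3)
        b = generate_cohort(5, seed=3)
        assert [p.seed for p in a] == [p.seed for p in b]
        profiles = {
            (p.profile.affected_channels, p.profile.affected_band) for p in a
        }
        assert len(profiles) == 5

    def test_singleton(self):
        cohort = generate_cohort(1, seed=0)
        assert len(cohort) == 1
        assert cohort[0].subject_id == "S1"

    def test_lateralized_profiles_present(self):
        cohort = generate_cohort(5, seed=0)
        sides = [p.profile.affected_channels[0][0] for p in cohort]
        assert "C" in "".join(sides)  # left (C3/CP1) and right (C2/CP2) both occur
        lefts = [p for p in cohort if "C3" in p.profile.affected_channels or "CP1" in p.profile.affected_channels]
        rights = [p for p in cohort if "C4" in p.profile.affected_channels or "CP2" in p.profile.affected_channels]
        assert lefts and rights
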