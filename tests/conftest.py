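import numpy as np
import pytest

from pedalbci.data_model import ProtocolParams
from pedalbci.synthetic import SubjectProfile, SynthParams, generate_session


@pytest.fixture(scope="session")
def tiny_session():
    """One-trial session for IO round-trips and bookkeeping tests."""
    params = SynthParams(
        profile=SubjectProfile(erd_depth=0.6),
        protocol=ProtocolParams(n_trials=1, cycles_per_trial=2, rest_s=7.0),
        seed=7,
    )
    return generate_session(params)


@pytest.fixture(scope="session")
def small_session():
    """Three-trial session, enough for cross-validation mechanics."""
    params = SynthParams(
        profile=SubjectProfile(affected_channels=("C3", "C1"), erd_depth=0.7, ers_gain=0.6),
        protocol=ProtocolParams(n_trials=3, cycles_per_trial=2, rest_s=7.0),
        seed=11,
    )
    return generate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
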