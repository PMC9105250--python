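import numpy as np
import pytest

from bscdetect.synthdata import (CHANNELS_4, SessionSpec, default_profiles,
                                 simulate_session)


@pytest.fixture(scope="session")
def ag_re_session():
    """A well-separated agitated-to-relaxed session, 420 s per phase."""
    spec = SessionSpec(subject="S01", channels=CHANNELS_4,
                       baseline_state="AG", stimulated_state="RE", seed=7)
    return simulate_session(spec)


@pytest.fixture(scope="session")
def short_ag_re_session():
    """A 120 s-per-phase agitated-to-relaxed session for fast detector runs."""
    spec = SessionSpec(subject="S01", channels=CHANNELS_4,
                       baseline_state="AG", stimulated_state="RE",
                       baseline_s=120, stimulation_s=120, seed=11)
    return simulate_session(spec)


def make_session(baseline="AG", stimulated="RE", seed=0, duration=120,
                 channels=CHANNELS_4, profiles=None, subject="S01"):
    spec = SessionSpec(subject=subject, channels=channels,
                       baseline_state=baseline, stimulated_state=stimulated,
                       baseline_s=duration, stimulation_s=duration, seed=seed)
    return simulate_session(spec, profiles)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
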