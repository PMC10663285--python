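import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reachdecode.eeg_preprocess import preprocess_session
from reachdecode.synthetic_session import SynthConfig, simulate_session

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """Two-block noisy session (one block per hand, all sources active)."""
    return simulate_session(SynthConfig(n_blocks=2, seed=77))


@pytest.fixture(scope="session")
def small_pre(small_session):
    return preprocess_session(small_session)


@pytest.fixture(scope="session")
def clean_ext_session():
    """Noise- and artifact-free two-block session, extrinsic source only."""
    cfg = SynthConfig(n_blocks=2, w_act=0.0, w_int=0.0, noise_sd=0.0, eog_amp=0.0, seed=101)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def clean_ext_pre(clean_ext_session):
    return preprocess_session(clean_ext_session, eog_mode="none")


@pytest.fixture(scope="session")
def clean_int_pre():
    """Preprocessed clean session with only the intrinsic (hand-mirrored)
    direction source."""
    cfg = SynthConfig(n_blocks=2, w_act=0.0, w_ext=0.0, noise_sd=0.0, eog_amp=0.0, seed=102)
    return preprocess_session(simulate_session(cfg), eog_mode="none")


@pytest.fixture(scope="session")
def clean_act_pre():
    """Preprocessed clean session with only the midline-symmetric action
    source."""
    cfg = SynthConfig(n_blocks=2, w_ext=0.0, w_int=0.0, noise_sd=0.0, eog_amp=0.0, seed=103)
    return preprocess_session(simulate_session(cfg), eog_mode="none")
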