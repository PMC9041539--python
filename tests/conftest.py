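import numpy as np
import pytest

from miconn.pipeline import preprocess_session
from miconn.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def tiny_session():
    """Down-scaled session: 2 s MI stage, 2 trials per hand, all conditions."""
    cfg = SynthConfig(n_trials_per_hand=2, stage_durations=(2.0, 2.0, 1.0), seed=42)
    rec, events, gt = generate_session(cfg)
    return cfg, rec, events, gt


@pytest.fixture(scope="session")
def tiny_trials(tiny_session):
    """Preprocessed (filtered, decimated, epoched) tiny session."""
    _, rec, _, _ = tiny_session
    return preprocess_session(rec, epoch_window=(-2.0, 3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
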