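import numpy as np
import pytest

from megdecode.containers import EpochSet
from megdecode.synth import SessionConfig, simulate_epochs


@pytest.fixture(scope="session")
def small_session():
    """Compact class-structured session shared by read-only tests."""
    cfg = SessionConfig(n_channels=24, sfreq=250, trials_per_class=20,
                        snr=10.0, seed=11)
    return simulate_epochs(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochset(data, labels, sfreq=250.0, window=(-1.0, 1.0)):
    return EpochSet(data=np.asarray(data, dtype=float),
                    labels=np.asarray(labels), sfreq=sfreq, window=window)
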