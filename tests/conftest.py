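import numpy as np
import pytest

from drowsydrive import SynthParams, generate_session
from drowsydrive.pipeline import preprocess


@pytest.fixture(scope="session")
def labeled_session():
    """Default-parameter 10 min alert + 10 min drowsy session at 512 Hz."""
    return generate_session(
        [("alert", 600), ("drowsy", 600)], fs=512, params=SynthParams(seed=0)
    )


@pytest.fixture(scope="session")
def preprocessed_session(labeled_session):
    """The same session after denoising and 512->128 Hz downsampling."""
    return preprocess(labeled_session)


@pytest.fixture(scope="session")
def short_session():
    """A 1-minute-per-state session for fast I/O and CLI tests."""
    return generate_session(
        [("alert", 60), ("drowsy", 60)], fs=512, params=SynthParams(seed=3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
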