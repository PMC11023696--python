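import numpy as np
import pytest

from vasoentrain import synthetic as synth


@pytest.fixture(scope="session")
def default_pair():
    """One default entrained photometry pair (900 s, 5 Hz, fully locked)."""
    ch1, ch2, gt = synth.gen_photometry_pair(seed=101)
    return ch1, ch2, gt


@pytest.fixture(scope="session")
def event_sessions():
    """Ten 10-min spontaneous-event sessions at the default event model."""
    out = []
    for seed in range(10):
        tr, gt = synth.gen_event_trace(synth.EventModel(), 600.0, 5.0, seed=seed)
        out.append((tr, gt))
    return out


@pytest.fixture(scope="session")
def small_vessel_stack():
    """A short default vessel stack (20 s) with its ground truth."""
    return synth.gen_vessel_stack(seed=7, duration=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
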