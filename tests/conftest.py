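import numpy as np
import pytest

from patchkit import events as ev
from patchkit import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def short_train():
    """10 s EPSC train with ground truth, shared across detection tests."""
    return syn.gen_epsc_train(duration_s=10.0, seed=42)


@pytest.fixture(scope="session")
def kernel_template(short_train):
    """Unit-peak template built from the generating kernel's reference taus."""
    trace, _ = short_train
    k = syn.epsc_kernel(0.2, 2.5, trace.dt)
    return ev.Template(k / np.max(k), trace.dt)


@pytest.fixture(scope="session")
def ap():
    """Packaged Wang-Buzsaki action-potential waveform (400 kHz grid)."""
    return syn.ap_waveform()
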