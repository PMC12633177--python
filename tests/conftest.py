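import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from dyadsync.ibs import WTCAnalyzer
from dyadsync.synthetic import DyadSpec, generate_dyad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_analyzer():
    """Analyzer matched to short (256-sample) test signals at 2 Hz."""
    return WTCAnalyzer(fs=2.0, fmin=0.1, fmax=0.5, voices=8)


@pytest.fixture(scope="session")
def quiet_dyad():
    """One artifact-free dyad with strong coupling, reused across tests."""
    spec = DyadSpec(
        n_channels_long=2,
        n_channels_short=1,
        duration_s=240.0,
        coupling_strength=0.6,
        artifact_rate=0.0,
        seed=202,
    )
    rec, gt = generate_dyad(spec, keep_neural=True)
    return spec, rec, gt
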