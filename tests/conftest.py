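import warnings

import numpy as np
import pytest

from gcflow.synth import Coupling, GroundTruthNetwork, Region

# liblinear emits ConvergenceWarning on deliberately non-separable
# shuffled-label fits; that is expected behaviour, not a test failure
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture
def two_channel_net():
    """Two single-channel regions with one awake-only 20 Hz coupling A -> B."""
    return GroundTruthNetwork(
        states=("awake", "unconscious"),
        regions=(Region("A", 1, band_hz=20.0), Region("B", 1, band_hz=12.0)),
        couplings=(Coupling("A", "B", band_hz=20.0, strength=0.5, state="awake"),),
    )


@pytest.fixture
def null_net():
    """Four two-channel regions, no couplings in either state."""
    return GroundTruthNetwork(
        states=("awake", "unconscious"),
        regions=(
            Region("FRT", 2, 8.0),
            Region("SMC", 2, 20.0),
            Region("TMP", 2, 44.0),
            Region("VIS", 2, 20.0),
        ),
        couplings=(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
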