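import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vsdi_retinomap.simulate import SimConfig, simulate_experiment


@pytest.fixture
def small_config():
    """Half-resolution protocol: 50 x 50 px at 50 Hz for 10 s."""
    return SimConfig(grid=(50, 50), frame_rate=50.0, duration=10.0)


@pytest.fixture
def small_sim(small_config):
    """One half-resolution noisy experiment at -10 dB."""
    import dataclasses

    cfg = dataclasses.replace(small_config, snr_db=-10.0, seed=7)
    return simulate_experiment(cfg)


@pytest.fixture
def small_clean(small_config):
    """One half-resolution noiseless experiment."""
    import dataclasses

    cfg = dataclasses.replace(small_config, snr_db=np.inf, seed=7)
    return simulate_experiment(cfg)
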