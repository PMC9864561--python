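import numpy as np
import pytest

from stmvpa import synth
from stmvpa.containers import default_times


@pytest.fixture(scope="session")
def gt_small():
    """4 categories x 12 features, half-shared geometry."""
    return synth.make_ground_truth(4, 12, 0.5, seed=11, noise_sd=1.0)


@pytest.fixture(scope="session")
def short_times():
    """9 time points, -100..220 ms at 25 Hz."""
    return default_times(-100, 220, 25)


@pytest.fixture(scope="session")
def epochs_small(gt_small, short_times):
    """Photo + drawing epochs, 8 trials per cell, 10 channels."""
    return synth.simulate_epochs(gt_small, 8, n_channels=10,
                                 times=short_times, seed=21,
                                 depictions=("photo", "drawing"))
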