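import numpy as np
import pytest

from audiomotor.hvd import TrialRecording


@pytest.fixture
def micro_trials():
    """Two trials, two fingers, two samples; worked through by hand.

    Trial 1: finger traces (1, 3) and (2, 2)  -> VF (3, 5)
    Trial 2: finger traces (2, 4) and (4, 2)  -> VF (6, 6)
    """
    t1 = TrialRecording(np.array([[1.0, 2.0], [3.0, 2.0]]), sample_rate=1.0)
    t2 = TrialRecording(np.array([[2.0, 4.0], [4.0, 2.0]]), sample_rate=1.0)
    return [t1, t2]


@pytest.fixture
def random_trials():
    """Five random four-finger trials of 50 samples (seeded)."""
    rng = np.random.default_rng(42)
    return [
        TrialRecording(rng.normal(5.0, 1.0, size=(50, 4)), sample_rate=100.0)
        for _ in range(5)
    ]
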