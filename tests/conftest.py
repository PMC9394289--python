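import numpy as np
import pytest

from crgcn import SynthConfig, deap32_montage, generate_trialset
from crgcn.montage import Montage


@pytest.fixture(scope="session")
def montage32():
    return deap32_montage()


@pytest.fixture(scope="session")
def line_montage():
    """Four collinear electrodes at unit spacing: hand-checkable distances."""
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    return Montage(("a", "b", "c", "d"), pos)


@pytest.fixture(scope="session")
def small_trialset():
    """8 alternating-class trials, full DEAP geometry, default effects."""
    cfg = SynthConfig(n_trials_per_subject=8, seed=42)
    labels = np.array([0, 1] * 4)
    return cfg, labels, generate_trialset(cfg, labels)
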