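import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from loomcd.danger_zone import build_zone
from loomcd.excitation import ExcitatoryState


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_zone():
    """64x48 frame, centered zone of radius 20."""
    return build_zone((48, 64), radius=20.0)


def make_state(e, threshold=0.7):
    """ExcitatoryState wrapper around a given (already filtered) e-layer."""
    e = np.asarray(e, dtype=float)
    return ExcitatoryState(e, np.zeros_like(e), threshold)
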